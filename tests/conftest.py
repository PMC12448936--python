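import numpy as np
import pytest
from hypothesis import settings

from olfevo.synthetic import MockPredictor, StructSimSpec, gen_structure_pair

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def struct_spec() -> StructSimSpec:
    """Default paralog-pair scenario: 2 causal sites, 30 decoys, jittered
    mock predictions."""
    return StructSimSpec(seed=11, prediction_noise_sd=0.04)


@pytest.fixture(scope="session")
def structure_pair(struct_spec):
    return gen_structure_pair(struct_spec)


@pytest.fixture(scope="session")
def mock_predictor(struct_spec):
    return MockPredictor(struct_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
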