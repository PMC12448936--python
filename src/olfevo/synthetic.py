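"""Seeded generators for every input family the pipeline consumes.

Each generator emulates one experimental data stream with known ground
truth so every stage is testable end to end:

* spike trains — homogeneous Poisson spiking at a baseline rate, with an
  elevated rate inside the odor-response window;
* dose-response series — logistic response plus Gaussian noise;
* structure pairs — an idealized 7-helix C-alpha bundle and a perturbed
  copy whose divergence is confined to Gaussian displacement fields
  centered on planted causal positions inside the S5-S6 helices, plus a
  deterministic mock structure-prediction backend that reproduces those
  fields whenever a mutated sequence carries the causal donor residue;
* behavior tables — binomial tube choices, exponential immobilization
  times observed on the 10-min assay grid, multinomial feeding scores.

All randomness flows through one named generator per call; the seed is a
required argument and identical spec + seed reproduces outputs exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .behavior import MobilityRecord
from .ephys import SpikeTrain
from .structure import RegionAnnotation, StructureModel

__all__ = [
    "EphysSimSpec",
    "DoseSimSpec",
    "StructSimSpec",
    "gen_spike_trains",
    "gen_dose_response",
    "gen_structure_pair",
    "MockPredictor",
    "gen_behavior_tables",
    "write_spike_trains_tsv",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Default 7-helix topology (1-based inclusive ranges).  The S5/S6 ranges
# are placed so that the canonical causal sites 181 and 307 fall inside
# them, mirroring the receptor-paralog geometry the screen operates on.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "S1": (30, 60),
    "S2": (75, 105),
    "S3": (118, 148),
    "S4": (153, 168),
    "S5": (170, 200),
    "S6": (290, 320),
    "S7": (335, 365),
}


# ---------------------------------------------------------------------------
# Electrophysiology
# ---------------------------------------------------------------------------

@dataclass
class EphysSimSpec:
    """Poisson spike-train simulation for a panel of sensilla.

    ``response_rate_map`` maps sensillum class -> odorant -> added
    spikes/s inside the response window [onset + 0.2, onset + 0.7] s.
    ``sensilla_per_class`` controls how many sensilla of each class are
    simulated; every sensillum is presented every odorant plus the
    solvent control, ``trial_count`` times each.
    """

    baseline_rate: float
    response_rate_map: dict[str, dict[str, float]]
    sensilla_per_class: dict[str, int] | None = None
    trial_count: int = 1
    stimulus_onset: float = 1.0
    trace_duration: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or not np.isfinite(self.baseline_rate):
            raise ValueError("baseline_rate must be finite and >= 0")
        for cls, odors in self.response_rate_map.items():
            for od, r in odors.items():
                if r < 0 or not np.isfinite(r):
                    raise ValueError(f"negative/non-finite rate for {cls}/{od}")
        if self.trial_count < 1:
            raise ValueError("trial_count must be >= 1")
        if self.sensilla_per_class is None:
            self.sensilla_per_class = {cls: 1 for cls in self.response_rate_map}


def _poisson_times(rng: np.random.Generator, rate: float, lo: float, hi: float) -> np.ndarray:
    if rate <= 0 or hi <= lo:
        return np.array([], dtype=float)
    n = rng.poisson(rate * (hi - lo))
    return np.sort(rng.uniform(lo, hi, size=n))


def gen_spike_trains(spec: EphysSimSpec) -> list[SpikeTrain]:
    """Simulate spike trains with a rate step inside the response window."""
    rng = np.random.default_rng(spec.seed)
    onset = spec.stimulus_onset
    win_lo, win_hi = onset + 0.2, onset + 0.7
    trains = []
    for cls in sorted(spec.response_rate_map):
        odor_rates = dict(spec.response_rate_map[cls])
        odor_rates["solvent"] = odor_rates.get("solvent", 0.0)
        for s in range(spec.sensilla_per_class[cls]):
            sensillum = f"{cls}-{s + 1}"
            for odorant in sorted(odor_rates):
                for trial in range(spec.trial_count):
                    base = _poisson_times(rng, spec.baseline_rate, 0.0, spec.trace_duration)
                    extra = _poisson_times(rng, odor_rates[odorant], win_lo, win_hi)
                    times = np.sort(np.concatenate([base, extra]))
                    trains.append(
                        SpikeTrain(
                            spike_times=times,
                            stimulus_onset=onset,
                            sensillum=sensillum,
                            odorant=odorant,
                            neuron="a",
                            trial_id=f"{sensillum}:{odorant}:{trial + 1}",
                            is_solvent=(odorant == "solvent"),
                        )
                    )
    return trains


def write_spike_trains_tsv(trains: list[SpikeTrain], path) -> None:
    """Write spike trains in the TSV dialect read by :mod:`olfevo.ephys`."""
    rows = [
        {
            "trial_id": t.trial_id,
            "sensillum": t.sensillum,
            "neuron": t.neuron,
            "odorant": t.odorant,
            "concentration": t.concentration,
            "onset_s": t.stimulus_onset,
            "is_solvent": t.is_solvent,
            "spike_times": ";".join(f"{x:.6f}" for x in t.spike_times),
        }
        for t in trains
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseSimSpec:
    """Logistic dose-response simulation for one chemical-species pair."""

    true_ec50: float
    hill: float = 1.0
    max_response: float = 100.0
    noise_sd: float = 0.0
    concentrations: tuple = tuple(np.logspace(-5, -2, 7))
    seed: int = 0
    chemical: str = "odorant"
    species: str = "species"

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size == 0:
            raise ValueError("empty concentration list")
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be positive and sorted ascending")
        if self.true_ec50 <= 0 or self.hill <= 0:
            raise ValueError("true_ec50 and hill must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.concentrations = tuple(conc)


def gen_dose_response(spec: DoseSimSpec):
    """Simulate a dose-response series from a 2-parameter logistic."""
    from .dose_response import DoseResponseSeries

    rng = np.random.default_rng(spec.seed)
    x = np.asarray(spec.concentrations)
    clean = spec.max_response / (1.0 + (spec.true_ec50 / x) ** spec.hill)
    noisy = clean + rng.normal(0.0, spec.noise_sd, size=x.size)
    noisy = np.clip(noisy, -spec.max_response, None)
    return DoseResponseSeries(x, noisy, chemical=spec.chemical, species=spec.species)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

@dataclass
class StructSimSpec:
    """Paired-paralog structure simulation with planted causal sites.

    ``causal_substitutions`` maps residue position -> (background residue,
    donor residue); each causal site carries a Gaussian C-alpha
    displacement field (sd ``field_width`` residues, peak
    ``perturb_amplitude`` Angstrom) confined to the S5-S6 helices.
    ``n_decoys`` structurally silent sequence differences are planted at
    non-causal positions.  ``prediction_noise_sd`` adds per-coordinate
    Gaussian jitter to every mock prediction (deterministic per
    sequence), emulating predictor reproducibility error.
    """

    n_residues: int = 400
    regions: dict[str, tuple[int, int]] = dc_field(
        default_factory=lambda: dict(DEFAULT_REGIONS)
    )
    causal_substitutions: dict[int, tuple[str, str]] = dc_field(
        default_factory=lambda: {181: ("A", "D"), 307: ("S", "P")}
    )
    n_decoys: int = 30
    perturb_amplitude: float = 4.2
    field_width: float = 3.0
    prediction_noise_sd: float = 0.0
    plddt_profile: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        ann = RegionAnnotation(self.regions)
        for name in ("S5", "S6"):
            if name not in self.regions:
                raise ValueError("regions must include S5 and S6")
        target = ann.union_mask(("S5", "S6"), self.n_residues)
        for pos in self.causal_substitutions:
            if not (1 <= pos <= self.n_residues) or not target[pos - 1]:
                raise ValueError(f"causal position {pos} outside the S5-S6 helices")
        if self.perturb_amplitude <= 0:
            raise ValueError("perturb_amplitude must be > 0")
        if self.plddt_profile is None:
            prof = np.full(self.n_residues, 90.0)
            ramp = min(15, self.n_residues // 4)
            prof[:ramp] = 50.0
            prof[self.n_residues - ramp :] = 50.0
            self.plddt_profile = prof
        else:
            self.plddt_profile = np.asarray(self.plddt_profile, dtype=float)
            if self.plddt_profile.shape != (self.n_residues,):
                raise ValueError("plddt_profile length must equal n_residues")
            if np.any((self.plddt_profile < 0) | (self.plddt_profile > 100)):
                raise ValueError("pLDDT must lie in [0, 100]")

    @property
    def annotation(self) -> RegionAnnotation:
        return RegionAnnotation(self.regions)


def _helix_bundle(spec: StructSimSpec) -> np.ndarray:
    """Idealized 7-helix C-alpha bundle.

    Helices stand parallel on a circle (alternating up/down, 1.5 A rise
    per residue, 100 deg turn, 2.3 A helical radius); inter-helix loops
    and termini are interpolated straight segments.
    """
    n = spec.n_residues
    coords = np.full((n, 3), np.nan)
    names = sorted(spec.regions, key=lambda k: spec.regions[k][0])
    bundle_radius = 11.0
    for k, name in enumerate(names):
        lo, hi = spec.regions[name]
        theta = 2.0 * np.pi * k / max(len(names), 1)
        cx, cy = bundle_radius * np.cos(theta), bundle_radius * np.sin(theta)
        length = hi - lo + 1
        idx = np.arange(length)
        direction = 1.0 if k % 2 == 0 else -1.0
        z = direction * (idx - length / 2.0) * 1.5
        phase = np.deg2rad(100.0) * idx
        coords[lo - 1 : hi] = np.column_stack(
            [cx + 2.3 * np.cos(phase), cy + 2.3 * np.sin(phase), z]
        )
    # interpolate loops/termini between anchored helix residues
    anchored = ~np.isnan(coords[:, 0])
    anchor_idx = np.flatnonzero(anchored)
    for axis in range(3):
        coords[:, axis] = np.interp(np.arange(n), anchor_idx, coords[anchor_idx, axis])
    return coords


def _displacement_fields(spec: StructSimSpec) -> dict[int, np.ndarray]:
    """Per-causal-site displacement fields, zero outside S5-S6."""
    target = spec.annotation.union_mask(("S5", "S6"), spec.n_residues)
    idx = np.arange(1, spec.n_residues + 1)
    fields = {}
    for pos in sorted(spec.causal_substitutions):
        rng = np.random.default_rng([spec.seed, pos])
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        envelope = spec.perturb_amplitude * np.exp(
            -((idx - pos) ** 2) / (2.0 * spec.field_width**2)
        )
        envelope[~target] = 0.0
        fields[pos] = envelope[:, None] * u[None, :]
    return fields


def _sequences(spec: StructSimSpec) -> tuple[str, str]:
    """(background, donor) sequences: causal + decoy differences planted."""
    rng = np.random.default_rng([spec.seed, 7919])
    bg = list(rng.choice(list(AMINO_ACIDS), size=spec.n_residues))
    donor = None
    for pos, (res_bg, res_donor) in spec.causal_substitutions.items():
        bg[pos - 1] = res_bg
    donor = bg.copy()
    for pos, (res_bg, res_donor) in spec.causal_substitutions.items():
        donor[pos - 1] = res_donor
    candidates = [i for i in range(spec.n_residues) if (i + 1) not in spec.causal_substitutions]
    decoy_idx = rng.choice(candidates, size=spec.n_decoys, replace=False)
    for i in decoy_idx:
        alternatives = [a for a in AMINO_ACIDS if a != bg[i]]
        donor[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(bg), "".join(donor)


def gen_structure_pair(spec: StructSimSpec) -> tuple[StructureModel, StructureModel]:
    """Background paralog model and its locally perturbed counterpart.

    The target structure equals the background plus the causal
    displacement fields (exactly identical outside S5-S6); the target
    sequence carries the causal substitutions plus ``n_decoys``
    structurally silent differences.
    """
    bg_seq, donor_seq = _sequences(spec)
    coords = _helix_bundle(spec)
    fields = _displacement_fields(spec)
    target_coords = coords + sum(fields.values(), np.zeros_like(coords))
    background = StructureModel(bg_seq, coords, spec.plddt_profile, model_id="background")
    target = StructureModel(donor_seq, target_coords, spec.plddt_profile, model_id="target")
    return background, target


class MockPredictor:
    """Deterministic stand-in structure-prediction backend.

    Maps a sequence to the background bundle plus, for every causal
    position whose residue equals the donor residue, that site's
    displacement field.  Decoy substitutions displace nothing.  With
    ``prediction_noise_sd`` > 0, per-coordinate Gaussian jitter seeded by
    (spec seed, CRC32 of the sequence) is added, so repeated calls on
    the same sequence return identical models.
    """

    def __init__(self, spec: StructSimSpec):
        self.spec = spec
        self._coords = _helix_bundle(spec)
        self._fields = _displacement_fields(spec)

    def __call__(self, sequence: str) -> StructureModel:
        spec = self.spec
        if len(sequence) != spec.n_residues:
            raise ValueError(
                f"sequence length {len(sequence)} != n_residues {spec.n_residues}"
            )
        coords = self._coords.copy()
        for pos, (_res_bg, res_donor) in spec.causal_substitutions.items():
            if sequence[pos - 1] == res_donor:
                coords = coords + self._fields[pos]
        if spec.prediction_noise_sd > 0:
            rng = np.random.default_rng(
                [spec.seed, zlib.crc32(sequence.encode()) & 0x7FFFFFFF]
            )
            coords = coords + rng.normal(0.0, spec.prediction_noise_sd, coords.shape)
        return StructureModel(sequence, coords, spec.plddt_profile, model_id="mock")


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------

CHOICE_TIME_GRID_MIN = (5, 10, 15, 20, 25, 30, 35, 65)
MOBILITY_TIME_GRID_MIN = (10, 20, 30, 40, 50, 60)


def gen_behavior_tables(
    choice_prob: float = 0.5,
    hazard_map: dict[str, float] | None = None,
    feeding_dist: dict[str, tuple] | None = None,
    seed: int = 0,
    n_choice_assays: int = 15,
    n_flies_choice: int = 12,
    n_vials_mobility: int = 10,
    n_flies_mobility: int = 10,
    n_feeding_vials: int = 14,
    n_flies_feeding: int = 12,
    choice_halflife_min: float = 10.0,
) -> dict:
    """Simulate the three behavioral assay tables.

    * choice — each fly commits to a side at an exponential time
      (half-life ``choice_halflife_min``) and picks the odor side with
      probability ``choice_prob``; counts on the 5..35/65-min grid;
    * mobility — immobilization is absorbing, times exponential with the
      per-arm hazard (events/min), right-censored at 60 min, observed on
      the 10-min grid;
    * feeding — per-vial multinomial counts over the 5 score categories
      for each condition in ``feeding_dist``.
    """
    if not 0.0 <= choice_prob <= 1.0:
        raise ValueError("choice_prob must be in [0, 1]")
    hazard_map = hazard_map if hazard_map is not None else {"control": 0.0, "treatment": 0.05}
    if any(h < 0 for h in hazard_map.values()):
        raise ValueError("hazards must be >= 0")
    feeding_dist = (
        feeding_dist
        if feeding_dist is not None
        else {"control": (0.1, 0.1, 0.2, 0.3, 0.3), "odor": (0.4, 0.2, 0.2, 0.1, 0.1)}
    )
    for cond, probs in feeding_dist.items():
        p = np.asarray(probs, dtype=float)
        if p.size != 5 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError(f"feeding_dist[{cond!r}] must be 5 probabilities summing to 1")
    rng = np.random.default_rng(seed)

    # --- positional choice ---
    lam = np.log(2.0) / choice_halflife_min
    choice_rows = []
    for assay in range(n_choice_assays):
        t_choice = rng.exponential(1.0 / lam, size=n_flies_choice)
        side_odor = rng.random(n_flies_choice) < choice_prob
        for t in CHOICE_TIME_GRID_MIN:
            chose = t_choice <= t
            choice_rows.append(
                {
                    "assay": assay + 1,
                    "time_min": t,
                    "odor": int((chose & side_odor).sum()),
                    "control": int((chose & ~side_odor).sum()),
                    "released": n_flies_choice,
                }
            )
    choice = pd.DataFrame(choice_rows)

    # --- mobility ---
    mobility_rows = []
    records = []
    for arm, hazard in sorted(hazard_map.items()):
        for vial in range(n_vials_mobility):
            if hazard > 0:
                t_event = rng.exponential(1.0 / hazard, size=n_flies_mobility)
            else:
                t_event = np.full(n_flies_mobility, np.inf)
            grid_event = np.ceil(t_event / 10.0) * 10.0  # first grid time scored immobile
            mobile = [int((grid_event > t).sum()) for t in MOBILITY_TIME_GRID_MIN]
            records.append(
                MobilityRecord(
                    arm=arm,
                    times_min=np.array(MOBILITY_TIME_GRID_MIN),
                    mobile=np.array(mobile),
                    total=n_flies_mobility,
                )
            )
            for t, m in zip(MOBILITY_TIME_GRID_MIN, mobile):
                mobility_rows.append(
                    {"arm": arm, "vial": vial + 1, "time_min": t, "mobile": m,
                     "total": n_flies_mobility}
                )
    mobility = pd.DataFrame(mobility_rows)

    # --- feeding ---
    feeding_rows = []
    for cond in sorted(feeding_dist):
        probs = np.asarray(feeding_dist[cond], dtype=float)
        for vial in range(n_feeding_vials):
            counts = rng.multinomial(n_flies_feeding, probs)
            feeding_rows.append(
                {
                    "condition": cond,
                    "vial": vial + 1,
                    "day": f"day{vial % 4 + 1}",
                    "n0": int(counts[0]),
                    "n025": int(counts[1]),
                    "n05": int(counts[2]),
                    "n1": int(counts[3]),
                    "n2": int(counts[4]),
                }
            )
    feeding = pd.DataFrame(feeding_rows)
    return {
        "choice": choice,
        "mobility": mobility,
        "mobility_records": records,
        "feeding": feeding,
    }


def write_fasta(sequences: dict[str, str], path) -> None:
    """Write sequences as FASTA."""
    from biotite.sequence.io.fasta import FastaFile

    ff = FastaFile()
    for name, seq in sequences.items():
        ff[name] = seq
    ff.write(str(path))
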