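"""Exact nonparametric tests against enumeration and permutation oracles."""

import numpy as np
import pytest
from scipy.stats import kruskal, kstest

from _oracles import (
    logrank_permutation_p,
    mwu_p_enumeration,
    signed_rank_p_enumeration,
)
from olfevo.stats import (
    kruskal_wallis_dunn,
    logrank,
    mann_whitney_u,
    signed_rank_one_sample,
)


class TestSignedRank:
    def test_all_positive_small_sample_one_sided(self):
        # every sign pattern with all ranks positive: p = 1 / 2^6
        r = signed_rank_one_sample([1, 2, 3, 4, 5, 6], mu0=0, alternative="greater")
        assert r.exact
        assert r.p_value == pytest.approx(1 / 64)

    def test_symmetric_sample_is_null_centered(self):
        r = signed_rank_one_sample([-3, -2, -1, 1, 2, 3.5], mu0=0)
        assert r.p_value > 0.8

    def test_all_values_equal_mu0_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_one_sample([5.0, 5.0], mu0=5.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 11))
            vals = rng.normal(0.3, 1.0, size=n)
            alt = rng.choice(["two-sided", "greater", "less"])
            r = signed_rank_one_sample(vals, mu0=0, alternative=alt)
            assert r.exact
            assert r.p_value == pytest.approx(
                signed_rank_p_enumeration(vals, 0, alt), abs=1e-12
            )

    def test_normal_approximation_near_exact_at_boundary(self, rng):
        for _ in range(10):
            vals = rng.normal(0.2, 1.0, size=25)
            exact = signed_rank_one_sample(vals, 0, "two-sided")
            approx = signed_rank_one_sample(vals, 0, "two-sided", exact_limit=0)
            assert exact.exact and not approx.exact
            assert abs(exact.p_value - approx.p_value) <= 0.01


class TestMannWhitney:
    def test_complete_separation_exact(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.exact
        assert r.statistic == 0
        assert r.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_identical_groups_no_evidence(self):
        r = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value > 0.9

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 8))
            m = int(rng.integers(3, 8))
            x = rng.normal(0, 1, size=n)
            y = rng.normal(0.5, 1, size=m)
            alt = rng.choice(["two-sided", "greater", "less"])
            r = mann_whitney_u(x, y, alternative=alt)
            assert r.exact
            assert r.p_value == pytest.approx(mwu_p_enumeration(x, y, alt), abs=1e-12)

    def test_normal_approximation_near_exact_at_boundary(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, size=10)
            y = rng.normal(0.4, 1, size=10)
            exact = mann_whitney_u(x, y)
            approx = mann_whitney_u(x, y, exact_limit=0)
            assert abs(exact.p_value - approx.p_value) <= 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestKruskalWallisDunn:
    def test_identical_groups_h_near_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        omnibus, _ = kruskal_wallis_dunn([g, g, g])
        assert omnibus.statistic == pytest.approx(0.0, abs=1e-9)

    def test_h_matches_hand_computation_and_scipy(self):
        # rank arithmetic done by hand: groups (1,2,3), (4,5,6), (7,8,9)
        # ranks are 1..9, rank sums 6, 15, 24:
        # H = 12/(9*10) * (36/3 + 225/3 + 576/3) - 3*10 = 7.2
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        omnibus, _ = kruskal_wallis_dunn(groups)
        assert omnibus.statistic == pytest.approx(7.2)
        assert omnibus.statistic == pytest.approx(kruskal(*groups).statistic)
        assert omnibus.p_value == pytest.approx(kruskal(*groups).pvalue)

    def test_tie_correction_matches_scipy(self, rng):
        groups = [rng.integers(0, 4, size=8).astype(float) for _ in range(3)]
        omnibus, _ = kruskal_wallis_dunn(groups)
        assert omnibus.statistic == pytest.approx(kruskal(*groups).statistic)

    def test_dunn_no_less_conservative_than_omnibus_under_null(self, rng):
        reject_omni = reject_dunn = 0
        for _ in range(500):
            groups = [rng.normal(size=10) for _ in range(3)]
            omnibus, pairs = kruskal_wallis_dunn(groups)
            reject_omni += omnibus.p_value < 0.05
            reject_dunn += min(p["p_adjusted"] for p in pairs) < 0.05
        assert reject_dunn <= reject_omni + 10

    def test_requires_three_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1.0], [2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([[1.0], [], [2.0]])


class TestLogrank:
    def test_identical_arms_statistic_zero(self):
        times = np.array([10, 20, 30, 60, 10, 20, 30, 60])
        events = np.array([1, 1, 1, 0, 1, 1, 1, 0])
        arm = np.array(["a"] * 4 + ["b"] * 4)
        r = logrank(times, events, arm)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)

    def test_single_event_time_matches_hand_computation(self):
        # n treatment flies all immobilized at t=10, n controls censored at
        # 60: O1-E1 = n/2, V = n^2 / (4 (2n - 1)), chi2 = 2n - 1
        n = 10
        times = np.array([10.0] * n + [60.0] * n)
        events = np.array([1] * n + [0] * n)
        arm = np.array(["treatment"] * n + ["control"] * n)
        r = logrank(times, events, arm)
        assert r.statistic == pytest.approx(2 * n - 1)

    def test_matches_permutation_null(self, rng):
        t1 = np.minimum(rng.exponential(25, 25), 60.0)
        t2 = np.minimum(rng.exponential(40, 25), 60.0)
        times = np.concatenate([t1, t2])
        events = (times < 60).astype(int)
        arm = np.array(["a"] * 25 + ["b"] * 25)
        p_chi2 = logrank(times, events, arm).p_value
        p_perm = logrank_permutation_p(times, events, arm, n_perm=2000, seed=5)
        assert abs(p_chi2 - p_perm) < 0.03

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            logrank([60, 60], [0, 0], ["a", "b"])


class TestTypeIError:
    """Empirical size close to nominal alpha = 0.05 under simulated nulls."""

    N_REPS = 500
    # binomial 99.7% band around 0.05 for 500 replicates
    LO, HI = 0.05 - 3 * np.sqrt(0.05 * 0.95 / 500), 0.05 + 3 * np.sqrt(0.05 * 0.95 / 500)

    def _check(self, rate: float) -> None:
        assert self.LO <= rate <= self.HI, f"empirical size {rate} outside binomial band"

    def test_signed_rank_size(self, rng):
        rejections = sum(
            signed_rank_one_sample(rng.normal(size=20), 0).p_value < 0.05
            for _ in range(self.N_REPS)
        )
        self._check(rejections / self.N_REPS)

    def test_mann_whitney_size(self, rng):
        # n = m = 12: null distribution fine-grained enough that the
        # nominal level is achievable (smaller exact samples are
        # conservative purely through discreteness)
        rejections = sum(
            mann_whitney_u(rng.normal(size=12), rng.normal(size=12)).p_value < 0.05
            for _ in range(self.N_REPS)
        )
        self._check(rejections / self.N_REPS)

    def test_kruskal_wallis_size(self, rng):
        rejections = sum(
            kruskal_wallis_dunn([rng.normal(size=12) for _ in range(3)])[0].p_value < 0.05
            for _ in range(self.N_REPS)
        )
        self._check(rejections / self.N_REPS)

    def test_logrank_size(self, rng):
        rejections = 0
        arm = np.array(["a"] * 40 + ["b"] * 40)
        for _ in range(self.N_REPS):
            t = np.minimum(rng.exponential(30, 80), 60.0)
            e = (t < 60).astype(int)
            rejections += logrank(t, e, arm).p_value < 0.05
        self._check(rejections / self.N_REPS)
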