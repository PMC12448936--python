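"""Nonparametric tests used throughout the pipeline.

All tests are implemented self-contained so that the exact (enumeration)
null distributions are available for small samples:

* one-sample Wilcoxon signed-rank (exact for n <= 25 without ties),
* Mann-Whitney U (exact for n + m <= 20 without ties),
* Kruskal-Wallis H with Dunn's post-hoc z tests,
* two-arm log-rank (Mantel-Cox).

Exact p-values are computed by dynamic programming over the rank-sum
distribution, which is equivalent to full enumeration of sign vectors /
group assignments but polynomial in n.  When ties are present (midranks)
or samples are larger, a tie-corrected normal approximation with
continuity correction is used and the ``exact`` flag is False.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "TestResult",
    "signed_rank_one_sample",
    "mann_whitney_u",
    "kruskal_wallis_dunn",
    "logrank",
]

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: str
    exact: bool
    n: tuple[int, ...]
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        self.p_value = min(self.p_value, 1.0)


def _check_alternative(alternative: str) -> str:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    return alternative


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_rank_counts(n: int) -> np.ndarray:
    """Number of sign assignments of ranks 1..n giving each W+ value.

    counts[w] = #{S subset of {1..n} : sum(S) = w}; the null distribution of
    W+ is counts / 2**n.
    """
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: max_w - r + 1].copy()
    return counts


def signed_rank_one_sample(
    values, mu0: float = 0.0, alternative: str = "two-sided", exact_limit: int = 25
) -> TestResult:
    """One-sample Wilcoxon signed-rank test against a hypothesized median.

    Zero differences (value == ``mu0``) are dropped (Wilcoxon convention).
    The statistic is W+, the sum of ranks of positive differences.  For
    n <= ``exact_limit`` with no tied absolute differences the p-value is
    exact; otherwise a tie-corrected normal approximation with continuity
    correction is used.

    ``alternative="greater"`` tests median > mu0.
    """
    alternative = _check_alternative(alternative)
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all values equal mu0; signed-rank test undefined")

    absd = np.abs(d)
    ranks = rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n

    if n <= exact_limit and not has_ties:
        counts = _signed_rank_counts(n)
        total = counts.sum()
        w = int(round(w_plus))
        p_ge = counts[w:].sum() / total
        p_le = counts[: w + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(w_plus, p, "wilcoxon_signed_rank", True, (n,))

    mean = n * (n + 1) / 4.0
    # tie correction on the variance (Lehmann)
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        p = norm.sf(z)
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        p = norm.cdf(z)
    else:
        z = (w_plus - mean - np.sign(w_plus - mean) * 0.5) / sd
        p = 2.0 * norm.sf(abs(z))
    return TestResult(w_plus, min(p, 1.0), "wilcoxon_signed_rank", False, (n,))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _mwu_counts(n: int, m: int) -> np.ndarray:
    """Null distribution counts of U for group sizes n, m (no ties).

    counts[u] = number of arrangements with U statistic u; equivalent to
    enumerating all C(n+m, n) group assignments.
    """
    max_u = n * m
    counts = np.zeros(max_u + 1, dtype=np.float64)
    counts[0] = 1.0
    # Gaussian-binomial recurrence: build the generating polynomial
    # prod_{j=1..n} (1 - q^(m+j)) / (1 - q^j)
    for j in range(1, n + 1):
        # multiply by 1/(1 - q^j): prefix sums with stride j
        for u in range(j, max_u + 1):
            counts[u] += counts[u - j]
        # multiply by (1 - q^(m+j))
        s = m + j
        for u in range(max_u, s - 1, -1):
            counts[u] -= counts[u - s]
    return counts


def mann_whitney_u(x, y, alternative: str = "two-sided", exact_limit: int = 20) -> TestResult:
    """Mann-Whitney U test for two independent samples.

    The statistic is U for the first sample (number of (x, y) pairs with
    x > y, counting ties as 1/2).  Exact p-values for n + m <=
    ``exact_limit`` without ties, otherwise tie-corrected normal
    approximation with continuity correction.
    """
    alternative = _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise ValueError("both groups must be nonempty")

    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    r_x = ranks[:n].sum()
    u_x = float(r_x - n * (n + 1) / 2.0)
    has_ties = np.unique(combined).size < n + m

    if n + m <= exact_limit and not has_ties:
        counts = _mwu_counts(n, m)
        total = counts.sum()
        u = int(round(u_x))
        p_ge = counts[u:].sum() / total
        p_le = counts[: u + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(u_x, p, "mann_whitney_u", True, (n, m))

    mean = n * m / 2.0
    nm = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (nm * (nm - 1))
    var = n * m / 12.0 * (nm + 1 - tie_term)
    sd = np.sqrt(var)
    if sd == 0:
        return TestResult(u_x, 1.0, "mann_whitney_u", False, (n, m))
    if alternative == "greater":
        p = norm.sf((u_x - mean - 0.5) / sd)
    elif alternative == "less":
        p = norm.cdf((u_x - mean + 0.5) / sd)
    else:
        z = (u_x - mean - np.sign(u_x - mean) * 0.5) / sd
        p = 2.0 * norm.sf(abs(z))
    return TestResult(u_x, min(p, 1.0), "mann_whitney_u", False, (n, m))


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_wallis_dunn(groups, correction: str = "bonferroni"):
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc comparisons.

    Parameters
    ----------
    groups : sequence of 1-d array-likes (>= 3 groups, all nonempty)
    correction : "bonferroni" or "none" — multiplicity adjustment applied
        to the Dunn pairwise p-values.

    Returns
    -------
    (TestResult, list of dict) — the omnibus result and one record per
    pair with keys ``pair``, ``z``, ``p_raw``, ``p_adjusted``.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError("correction must be 'bonferroni' or 'none'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")

    sizes = [g.size for g in groups]
    big_n = int(sum(sizes))
    combined = np.concatenate(groups)
    ranks = rankdata(combined)

    # omnibus H with tie correction
    offset = 0
    rank_sums = []
    for g in groups:
        rank_sums.append(ranks[offset : offset + g.size].sum())
        offset += g.size
    h = 12.0 / (big_n * (big_n + 1)) * sum(
        rs**2 / ni for rs, ni in zip(rank_sums, sizes)
    ) - 3 * (big_n + 1)
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_corr = 1.0 - (tie_counts**3 - tie_counts).sum() / (big_n**3 - big_n)
    if tie_corr > 0:
        h /= tie_corr
    df = len(groups) - 1
    p_omni = chi2.sf(h, df)
    omnibus = TestResult(h, p_omni, "kruskal_wallis", False, tuple(sizes), {"df": df})

    # Dunn pairwise
    mean_ranks = [rs / ni for rs, ni in zip(rank_sums, sizes)]
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (big_n - 1))
    base_var = big_n * (big_n + 1) / 12.0 - tie_term
    pairs = []
    k = len(groups)
    n_pairs = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p_raw = 2.0 * norm.sf(abs(z))
            p_adj = min(1.0, p_raw * n_pairs) if correction == "bonferroni" else p_raw
            pairs.append({"pair": (i, j), "z": z, "p_raw": p_raw, "p_adjusted": p_adj})
    return omnibus, pairs


# ---------------------------------------------------------------------------
# Log-rank (Mantel-Cox)
# ---------------------------------------------------------------------------

def logrank(times, events, arm) -> TestResult:
    """Two-arm log-rank (Mantel-Cox) test.

    Parameters
    ----------
    times : event or censoring times
    events : 1 if the event (e.g. immobilization) was observed, 0 if
        right-censored
    arm : group label per observation (exactly two distinct labels)

    The chi-square statistic (1 df) is ``(O1 - E1)^2 / V`` summed over
    distinct event times with the hypergeometric variance.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    arm = np.asarray(arm)
    labels = np.unique(arm)
    if labels.size != 2:
        raise ValueError("logrank requires exactly two arms")
    if events.sum() == 0:
        raise ValueError("no events in either arm")
    g1 = arm == labels[0]

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n_t = at_risk.sum()
        n1_t = (at_risk & g1).sum()
        d_t = ((times == t) & (events == 1)).sum()
        d1_t = ((times == t) & (events == 1) & g1).sum()
        e1 = d_t * n1_t / n_t
        o_minus_e += d1_t - e1
        if n_t > 1:
            var += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    if var == 0:
        return TestResult(0.0, 1.0, "logrank_mantel_cox", False, (int(g1.sum()), int((~g1).sum())))
    stat = o_minus_e**2 / var
    p = chi2.sf(stat, 1)
    return TestResult(
        float(stat),
        float(p),
        "logrank_mantel_cox",
        False,
        (int(g1.sum()), int((~g1).sum())),
        {"observed_minus_expected": float(o_minus_e), "variance": float(var)},
    )
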