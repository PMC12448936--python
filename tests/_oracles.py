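"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths they check: exact test p-values
come from full enumeration, the optimal-superposition RMSD from a
quaternion search, the log-rank null from label permutation.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import minimize
from scipy.stats import rankdata


def signed_rank_p_enumeration(values, mu0: float, alternative: str) -> float:
    """Exact signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws, dtype=float)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    p_le = np.mean(ws <= w_obs + 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def mwu_p_enumeration(x, y, alternative: str) -> float:
    """Exact Mann-Whitney p by enumerating all group assignments."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2.0
    us = []
    for comb in combinations(range(n + m), n):
        u = ranks[list(comb)].sum() - n * (n + 1) / 2.0
        us.append(u)
    us = np.asarray(us)
    p_ge = np.mean(us >= u_obs - 1e-9)
    p_le = np.mean(us <= u_obs + 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def _quat_to_rot(q: np.ndarray) -> np.ndarray:
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_grid_rmsd(mobile: np.ndarray, reference: np.ndarray, seed: int = 0) -> float:
    """Minimum RMSD over rigid motions via quaternion search + refinement.

    Proper rotations only (unit quaternions); the optimal translation for
    any rotation matches the centroids.  Independent of the SVD route.
    """
    mobile = mobile - mobile.mean(axis=0)
    reference = reference - reference.mean(axis=0)

    def rmsd_of(q):
        rot = _quat_to_rot(np.asarray(q, dtype=float))
        moved = mobile @ rot.T
        return np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(4000, 4))
    best_q, best_r = None, np.inf
    for q in quats:
        r = rmsd_of(q)
        if r < best_r:
            best_q, best_r = q, r
    res = minimize(
        rmsd_of,
        best_q / np.linalg.norm(best_q),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000, "maxfev": 20000},
    )
    return float(min(best_r, res.fun))


def logrank_permutation_p(times, events, arm, n_perm: int, seed: int) -> float:
    """Permutation-null p-value for the log-rank statistic."""
    from olfevo.stats import logrank

    obs = logrank(times, events, arm).statistic
    rng = np.random.default_rng(seed)
    arm = np.asarray(arm)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(arm)
        if logrank(times, events, perm).statistic >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
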