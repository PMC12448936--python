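"""EC50 estimation with a two-parameter / four-parameter / fallback policy.

Dose-response series (odorant concentration vs control-subtracted
spikes/s) are fitted with logistic curves in log10-concentration space:

* two-parameter (2P), on responses normalized to [0, 100] within the
  chemical-species pair:   y = 100 / (1 + (EC50 / x) ** h)
* four-parameter (4P), on raw responses with free floor and ceiling:
  y = d + (a - d) / (1 + (EC50 / x) ** h)

The estimation policy mirrors common practice for spike dose-response
data: try the normalized 2P fit first; fall back to the 4P fit when the
2P fit fails or when the chemical is on a forced-4P list (used for
odorants whose highest tested concentration does not reach saturation);
when both fits fail, report the minimum observed response value under a
distinct method tag instead of a concentration.

"Failed to fit" is operationalized as optimizer non-convergence, an EC50
outside [min tested concentration / 100, max tested concentration x 100],
or a non-positive Hill slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

__all__ = [
    "DoseResponseSeries",
    "EC50Result",
    "DoseResponseModel",
    "FitPolicy",
    "normalize_series",
    "fit_two_param",
    "fit_four_param",
    "estimate_ec50",
]

_HILL_RESTARTS = (0.5, 1.0, 2.0)


class NormalizationError(ValueError):
    """Raised when a series has no positive dynamic range to normalize."""


@dataclass
class DoseResponseSeries:
    """Concentration-response pairs for one chemical-species pair."""

    concentrations: np.ndarray
    responses: np.ndarray
    chemical: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.size != self.responses.size:
            raise ValueError("concentrations and responses differ in length")
        if self.concentrations.size == 0:
            raise ValueError("empty dose-response series")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be strictly positive")

    @property
    def n_distinct(self) -> int:
        return int(np.unique(self.concentrations).size)


@dataclass
class EC50Result:
    """Fitted EC50 and diagnostics.

    ``ec50`` is a vol/vol concentration except when ``method`` is
    ``min_value_fallback``, where the reported value is the minimum
    observed response within the chemical-species group (no logistic
    could be fitted).
    """

    ec50: float
    method: str
    hill: float = np.nan
    bottom: float = np.nan
    top: float = np.nan
    converged: bool = False
    residual_norm: float = np.nan
    chemical: str = ""
    species: str = ""
    details: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "EC50 estimation".center(46),
            "=" * 46,
            f"{'chemical:':<18}{self.chemical or '-'}",
            f"{'species:':<18}{self.species or '-'}",
            f"{'method:':<18}{self.method}",
            f"{'converged:':<18}{self.converged}",
        ]
        if self.method == "min_value_fallback":
            lines.append(f"{'min response:':<18}{self.ec50:.4g} spikes/s")
        else:
            lines += [
                f"{'EC50 (vol/vol):':<18}{self.ec50:.4g}",
                f"{'Hill slope:':<18}{self.hill:.4g}",
                f"{'bottom:':<18}{self.bottom:.4g}",
                f"{'top:':<18}{self.top:.4g}",
                f"{'residual norm:':<18}{self.residual_norm:.4g}",
            ]
        return "\n".join(lines)


@dataclass
class FitPolicy:
    """Branching policy for :func:`estimate_ec50`.

    ``force_four_param`` lists chemicals always sent to the raw 4P fit
    (odorants not reaching saturation at the highest tested
    concentration).
    """

    force_four_param: frozenset = frozenset()

    def forces_4p(self, chemical: str) -> bool:
        return chemical in self.force_four_param


def normalize_series(series: DoseResponseSeries) -> DoseResponseSeries:
    """Normalize responses to [0, 100] within the chemical-species pair.

    Negative responses are floored at 0, then scaled so the largest
    response maps to 100.  Raises :class:`NormalizationError` when no
    response is positive (signals the fallback path).
    """
    r = series.responses
    rmax = r.max()
    if rmax <= 0:
        raise NormalizationError(
            f"series {series.chemical}/{series.species}: all responses <= 0"
        )
    scaled = np.clip(r, 0.0, None) / rmax * 100.0
    return DoseResponseSeries(
        series.concentrations.copy(), scaled, series.chemical, series.species
    )


def _logistic2(logx: np.ndarray, log_ec50: float, h: float) -> np.ndarray:
    return 100.0 / (1.0 + 10.0 ** (h * (log_ec50 - logx)))


def _logistic4(
    logx: np.ndarray, log_ec50: float, h: float, bottom: float, top: float
) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (h * (log_ec50 - logx)))


def _initial_log_ec50(logx: np.ndarray, y: np.ndarray) -> float:
    half = (y.min() + y.max()) / 2.0
    return float(logx[np.argmin(np.abs(y - half))])


def _sorted_xy(series: DoseResponseSeries) -> tuple[np.ndarray, np.ndarray]:
    # canonical ordering makes the fit exactly invariant to point order
    order = np.lexsort((series.responses, series.concentrations))
    return np.log10(series.concentrations[order]), series.responses[order]


def _fit_ok(series: DoseResponseSeries, ec50: float, hill: float) -> bool:
    cmin, cmax = series.concentrations.min(), series.concentrations.max()
    return bool(hill > 0 and cmin / 100.0 <= ec50 <= cmax * 100.0)


def fit_two_param(series: DoseResponseSeries) -> EC50Result:
    """Two-parameter logistic fit of a normalized series.

    Expects responses on the 0-100 normalized scale.  Non-convergence is
    reported via ``converged=False``, never raised.
    """
    if series.n_distinct < 3:
        raise ValueError("need >= 3 distinct concentrations to fit")
    logx, y = _sorted_xy(series)
    best = None
    for h0 in _HILL_RESTARTS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _logistic2,
                    logx,
                    y,
                    p0=[_initial_log_ec50(logx, y), h0],
                    maxfev=20000,
                    xtol=1e-14,
                    ftol=1e-14,
                )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(y - _logistic2(logx, *popt)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return EC50Result(
            np.nan, "two_param_normalized", converged=False,
            chemical=series.chemical, species=series.species,
        )
    (log_ec50, hill), resid = best
    ec50 = 10.0**log_ec50
    return EC50Result(
        ec50, "two_param_normalized", hill=hill, bottom=0.0, top=100.0,
        converged=_fit_ok(series, ec50, hill), residual_norm=resid,
        chemical=series.chemical, species=series.species,
    )


def fit_four_param(series: DoseResponseSeries) -> EC50Result:
    """Four-parameter logistic fit of a raw (unnormalized) series.

    Floor and ceiling are free parameters; negative responses are kept
    as-is.
    """
    if series.n_distinct < 3:
        raise ValueError("need >= 3 distinct concentrations to fit")
    logx, y = _sorted_xy(series)
    best = None
    for h0 in _HILL_RESTARTS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(
                    _logistic4,
                    logx,
                    y,
                    p0=[_initial_log_ec50(logx, y), h0, float(y.min()), float(y.max())],
                    maxfev=40000,
                    xtol=1e-14,
                    ftol=1e-14,
                )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(y - _logistic4(logx, *popt)))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return EC50Result(
            np.nan, "four_param", converged=False,
            chemical=series.chemical, species=series.species,
        )
    (log_ec50, hill, bottom, top), resid = best
    ec50 = 10.0**log_ec50
    # a collapsed dynamic range (top ~ bottom) leaves the EC50
    # unidentifiable even when the optimizer reports success
    identifiable = abs(top - bottom) > 1e-6 * max(1.0, abs(top), abs(bottom))
    return EC50Result(
        ec50, "four_param", hill=hill, bottom=bottom, top=top,
        converged=identifiable and _fit_ok(series, ec50, hill), residual_norm=resid,
        chemical=series.chemical, species=series.species,
    )


def estimate_ec50(series: DoseResponseSeries, policy: FitPolicy | None = None) -> EC50Result:
    """Apply the 2P -> 4P -> minimum-value estimation policy."""
    policy = policy or FitPolicy()
    if not policy.forces_4p(series.chemical):
        try:
            res2 = fit_two_param(normalize_series(series))
        except NormalizationError:
            res2 = None
        if res2 is not None and res2.converged:
            res2.chemical, res2.species = series.chemical, series.species
            return res2
    res4 = fit_four_param(series)
    if res4.converged:
        return res4
    min_resp = float(series.responses.min())
    return EC50Result(
        min_resp, "min_value_fallback", converged=False,
        chemical=series.chemical, species=series.species,
        details={"note": "no logistic converged; minimum observed response reported"},
    )


class DoseResponseModel:
    """Logistic dose-response model for one chemical-species pair.

    Thin model object wrapping the functional fitting API: construct from
    arrays or a DataFrame, call :meth:`fit` to obtain an
    :class:`EC50Result`.
    """

    def __init__(self, series: DoseResponseSeries, policy: FitPolicy | None = None):
        self.series = series
        self.policy = policy or FitPolicy()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        chemical: str | None = None,
        species: str | None = None,
        policy: FitPolicy | None = None,
    ) -> "DoseResponseModel":
        """Build from a tidy frame with columns
        chemical, species, concentration, response."""
        sub = df
        if chemical is not None:
            sub = sub[sub["chemical"] == chemical]
        if species is not None:
            sub = sub[sub["species"] == species]
        if sub.empty:
            raise ValueError("no rows match the requested chemical/species")
        series = DoseResponseSeries(
            sub["concentration"].to_numpy(),
            sub["response"].to_numpy(),
            chemical=chemical or str(sub["chemical"].iloc[0]),
            species=species or str(sub["species"].iloc[0]),
        )
        return cls(series, policy)

    def fit(self, method: str = "policy") -> EC50Result:
        """Fit the model.

        ``method`` is "policy" (default branching), "two_param", or
        "four_param".
        """
        if method == "policy":
            return estimate_ec50(self.series, self.policy)
        if method == "two_param":
            return fit_two_param(normalize_series(self.series))
        if method == "four_param":
            return fit_four_param(self.series)
        raise ValueError(f"unknown method {method!r}")
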