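"""Behavioral indices: immobility, positional choice, food consumption.

Three assays quantify a fly's response to an odorant it can smell but
not touch:

* immobility — % of mobile flies counted every 10 min up to 1 h;
  arms are compared with the log-rank (Mantel-Cox) test, treating the
  first time point at which a fly is scored immobile as its event time
  and flies still mobile at 60 min as right-censored;
* positional choice — flies distribute between an odor-side tube, a
  control-side tube, and the release section; the % that made a choice
  and the % on the odor side are tested against the 50% random-choice
  null with one-sample signed-rank tests;
* consumption — a 5-point blue-dye feeding score per vial, normalized
  to same-day, same-genotype control vials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MobilityRecord",
    "ChoiceCount",
    "FeedingVial",
    "percent_mobile",
    "mobility_to_survival",
    "choice_metrics",
    "apply_exclusion",
    "feeding_score",
    "normalize_feeding",
]

MOBILITY_GRID_MIN = (10, 20, 30, 40, 50, 60)
CHOICE_EXCLUSION_PCT = 40.0


@dataclass
class MobilityRecord:
    """Mobile-fly counts for one vial on the 10-min observation grid."""

    arm: str
    times_min: np.ndarray
    mobile: np.ndarray
    total: int

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=int)
        self.mobile = np.asarray(self.mobile, dtype=int)
        if self.total <= 0:
            raise ValueError("total flies must be positive")
        if np.any(self.mobile > self.total) or np.any(self.mobile < 0):
            raise ValueError("mobile counts must be within [0, total]")
        if np.any(np.diff(self.mobile) > 0):
            raise ValueError("mobile counts must be non-increasing (immobility is absorbing)")


@dataclass
class ChoiceCount:
    """Fly counts at one time point of a positional olfactory assay."""

    time_min: int
    odor: int
    control: int
    released: int

    def __post_init__(self) -> None:
        if min(self.odor, self.control, self.released) < 0:
            raise ValueError("counts must be non-negative")
        if self.odor + self.control > self.released:
            raise ValueError("choosers exceed flies released")


@dataclass
class FeedingVial:
    """Per-category fly counts of the 5-point feeding score for one vial."""

    n0: int
    n025: int
    n05: int
    n1: int
    n2: int
    day: str = ""
    genotype: str = ""
    odor: str = ""

    @property
    def total(self) -> int:
        return self.n0 + self.n025 + self.n05 + self.n1 + self.n2


def percent_mobile(record: MobilityRecord) -> np.ndarray:
    """Percent mobile flies at each observation time."""
    return 100.0 * record.mobile / record.total


def mobility_to_survival(records: list[MobilityRecord]):
    """Expand mobility records to (times, events, arm) per fly.

    A fly's event time is the first grid time at which it is scored
    immobile; flies mobile at the last observation are right-censored
    there.  Output feeds :func:`olfevo.stats.logrank`.
    """
    times, events, arms = [], [], []
    for rec in records:
        prev = rec.total
        for t, m in zip(rec.times_min, rec.mobile):
            newly_immobile = prev - m
            times.extend([t] * newly_immobile)
            events.extend([1] * newly_immobile)
            arms.extend([rec.arm] * newly_immobile)
            prev = m
        t_end = int(rec.times_min[-1])
        times.extend([t_end] * prev)
        events.extend([0] * prev)
        arms.extend([rec.arm] * prev)
    return np.asarray(times), np.asarray(events), np.asarray(arms)


def choice_metrics(count: ChoiceCount) -> tuple[float, float]:
    """(% made a choice, % on the odor side).

    % made choice = (odor + control) / released x 100.
    % odor side = odor / (odor + control) x 100, NaN when no fly chose.
    """
    if count.released == 0:
        raise ValueError("no flies released")
    chose = count.odor + count.control
    pct_choice = 100.0 * chose / count.released
    pct_odor = 100.0 * count.odor / chose if chose > 0 else float("nan")
    return pct_choice, pct_odor


def apply_exclusion(assay: list[ChoiceCount]) -> bool:
    """Whether a positional assay should be kept.

    Discarded (returns False) only when fewer than 40% of flies made a
    choice at every time point; a single time point at >= 40% keeps the
    assay.
    """
    if not assay:
        raise ValueError("empty assay")
    return any(choice_metrics(c)[0] >= CHOICE_EXCLUSION_PCT for c in assay)


def feeding_score(vial: FeedingVial) -> float:
    """Weighted mean of the 5-point dye scale, in [0, 2]."""
    if vial.total == 0:
        raise ValueError("vial has no flies")
    weighted = (
        0.0 * vial.n0 + 0.25 * vial.n025 + 0.5 * vial.n05 + 1.0 * vial.n1 + 2.0 * vial.n2
    )
    return weighted / vial.total


def normalize_feeding(
    test_vials: list[FeedingVial], control_vials: list[FeedingVial]
) -> pd.DataFrame:
    """Normalize test-vial feeding scores by paired same-day control means.

    Pairing key is (day, genotype).  The downstream test of the
    normalized scores is a one-sample signed-rank against 1 (no
    aversion/enhancement).  Raises when a test vial has no paired
    control.
    """
    ctrl = pd.DataFrame(
        {
            "day": [v.day for v in control_vials],
            "genotype": [v.genotype for v in control_vials],
            "score": [feeding_score(v) for v in control_vials],
        }
    )
    ctrl_means = ctrl.groupby(["day", "genotype"])["score"].mean()
    rows = []
    for v in test_vials:
        key = (v.day, v.genotype)
        if key not in ctrl_means.index:
            raise ValueError(f"no control vial for day={v.day!r}, genotype={v.genotype!r}")
        rows.append(
            {
                "day": v.day,
                "genotype": v.genotype,
                "odor": v.odor,
                "score": feeding_score(v),
                "normalized": feeding_score(v) / ctrl_means[key],
            }
        )
    return pd.DataFrame(rows)
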