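"""Spike-response quantification and sensilla classification.

Single-sensillum recordings (SSR) yield timestamped extracellular spikes
from the one or two olfactory sensory neurons (OSNs) housed in a
cuticular sensillum.  The odor-evoked response is quantified as the net
number of spikes per second: spikes in a 0.5-s window starting 0.2 s
after stimulus onset, minus spikes in the 0.5 s preceding onset, doubled
to express the difference per second.  Responses are then corrected for
the solvent control, and sensilla are grouped into functional classes
from their response profiles across odorants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "SpikeTrain",
    "net_response",
    "control_subtract",
    "spike_ratio",
    "classify_sensilla",
    "read_spike_trains_tsv",
]

RESPONSE_DELAY_S = 0.2    # response window starts this long after stimulus onset
WINDOW_S = 0.5            # length of both the response and baseline windows


@dataclass
class SpikeTrain:
    """Spike timestamps for one odorant presentation.

    ``spike_times`` are seconds from trace start, sorted ascending.  The
    stimulus is a 1-s air pulse beginning at ``stimulus_onset``; the onset
    must leave room for the 0.5-s baseline window.
    """

    spike_times: np.ndarray
    stimulus_onset: float
    sensillum: str
    odorant: str
    concentration: float = 1e-2
    neuron: str = "a"
    trial_id: str = ""
    is_solvent: bool = False
    stimulus_duration: float = 1.0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted ascending")
        if self.spike_times.size and self.spike_times[0] < 0:
            raise ValueError("spike_times must be non-negative")
        if self.stimulus_onset < WINDOW_S:
            raise ValueError(
                f"stimulus_onset must be >= {WINDOW_S} s so a baseline window exists"
            )


def _count(times: np.ndarray, lo: float, hi: float) -> int:
    # closed-open [lo, hi): a spike exactly on the upper edge belongs to
    # the next window
    return int(np.count_nonzero((times >= lo) & (times < hi)))


def net_response(train: SpikeTrain) -> float:
    """Net odor-evoked response in spikes/s (may be negative).

    2 x (spikes in [onset+0.2, onset+0.7) - spikes in [onset-0.5, onset)).
    """
    t0 = train.stimulus_onset
    resp = _count(train.spike_times, t0 + RESPONSE_DELAY_S, t0 + RESPONSE_DELAY_S + WINDOW_S)
    base = _count(train.spike_times, t0 - WINDOW_S, t0)
    return 2.0 * (resp - base)


def control_subtract(trains: list[SpikeTrain]) -> pd.DataFrame:
    """Build a control-subtracted response panel from spike trains.

    For every sensillum, the mean net response to the solvent control is
    subtracted from each odorant's net response.  Returns a DataFrame
    indexed by sensillum with one column per odorant (mean across
    presentations of that odorant); the solvent column is consumed by the
    subtraction and does not appear.

    Raises ``ValueError`` naming the sensillum if it has no solvent trial.
    """
    if not trains:
        raise ValueError("no spike trains given")
    rows = [
        {
            "sensillum": t.sensillum,
            "odorant": t.odorant,
            "is_solvent": t.is_solvent,
            "net": net_response(t),
        }
        for t in trains
    ]
    df = pd.DataFrame(rows)
    panels = {}
    for sens, grp in df.groupby("sensillum", sort=True):
        solvent = grp.loc[grp["is_solvent"], "net"]
        if solvent.empty:
            raise ValueError(f"sensillum {sens!r} has no solvent control trial")
        baseline = solvent.mean()
        odors = grp.loc[~grp["is_solvent"]]
        panels[sens] = odors.groupby("odorant")["net"].mean() - baseline
    panel = pd.DataFrame(panels).T
    panel.index.name = "sensillum"
    return panel


def spike_ratio(r_bitc: float, r_ghex: float) -> float:
    """BITC / (BITC + gamma-hexalactone) response ratio.

    Quantifies how strongly a receptor favors the isothiocyanate over the
    fruit odorant.  Control-subtracted responses can be negative (the
    fruit odorant occasionally responds below solvent), which can drive
    the denominator to zero or below; the ratio is then undefined and NaN
    is returned rather than raising.
    """
    denom = r_bitc + r_ghex
    if denom <= 0:
        return float("nan")
    return r_bitc / denom


def classify_sensilla(panel: pd.DataFrame, n_classes: int = 3) -> pd.Series:
    """Partition sensilla into functional classes from response profiles.

    Agglomerative clustering (Ward linkage, Euclidean distance) of the
    control-subtracted response vectors, cut at ``n_classes``.  Labels are
    canonicalized so class 1 is the one containing the alphabetically
    first sensillum, making the output stable under row permutation.
    """
    if panel.isna().any().any():
        raise ValueError("panel has missing odorant responses; complete rows required")
    n = len(panel)
    if n_classes > n:
        raise ValueError(f"n_classes={n_classes} exceeds number of sensilla ({n})")
    if n_classes == 1 or n == 1:
        return pd.Series(1, index=panel.index, name="class")
    order = np.argsort(panel.index.to_numpy())
    x = panel.to_numpy(dtype=float)[order]
    raw = fcluster(linkage(x, method="ward"), n_classes, criterion="maxclust")
    # relabel in order of first appearance over the sorted index
    remap: dict[int, int] = {}
    canon = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        canon[i] = remap[lab]
    out = pd.Series(0, index=panel.index, name="class")
    out.iloc[order] = canon
    return out


def read_spike_trains_tsv(path) -> list[SpikeTrain]:
    """Read the spike-train TSV dialect written by the synthetic generator.

    Columns: trial_id, sensillum, neuron, odorant, concentration, onset_s,
    is_solvent, spike_times (semicolon-separated seconds).
    """
    df = pd.read_csv(path, sep="\t", dtype={"trial_id": str, "sensillum": str})
    trains = []
    for _, row in df.iterrows():
        raw = row["spike_times"]
        times = (
            np.array([], dtype=float)
            if pd.isna(raw) or raw == ""
            else np.array([float(v) for v in str(raw).split(";")])
        )
        trains.append(
            SpikeTrain(
                spike_times=times,
                stimulus_onset=float(row["onset_s"]),
                sensillum=str(row["sensillum"]),
                odorant=str(row["odorant"]),
                concentration=float(row["concentration"]),
                neuron=str(row.get("neuron", "a")),
                trial_id=str(row["trial_id"]),
                is_solvent=bool(row["is_solvent"]),
            )
        )
    return trains
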