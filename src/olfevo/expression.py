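"""Count-table summaries: RPM, low-expression filtering, FISH cell ratios.

Gene-level read counts from maxillary-palp RNA-seq are normalized to
reads per million (RPM) against the library size, odorant-receptor genes
below a median log2(RPM + 1) threshold across replicates are excluded,
and in-situ cell counts are summarized as the ratio of receptor-positive
to Orco-positive (total) olfactory sensory neurons per animal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import TestResult, mann_whitney_u

__all__ = ["rpm", "filter_low_expression", "cellcount_ratio"]


def rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization of a gene x sample count table.

    The denominator is the column sum over all genes present in the
    table (all counted genes, not only the receptor family).
    """
    counts = counts.astype(float)
    if (counts < 0).any().any():
        raise ValueError("negative counts")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size in samples: {bad}")
    return counts / lib * 1e6


def filter_low_expression(
    rpm_table: pd.DataFrame,
    groups: dict[str, list[str]] | None = None,
    threshold: float = 1.0,
    require_all_groups: bool = False,
) -> list[str]:
    """Genes passing the median log2(RPM + 1) expression filter.

    A gene is excluded when its median log2(RPM + 1) across replicates is
    strictly below ``threshold`` (default 1, i.e. median RPM below 1).
    With ``groups`` mapping group name -> sample columns, a gene is
    retained if it passes in at least one group (or in every group when
    ``require_all_groups``).
    """
    log2t = np.log2(rpm_table + 1.0)
    if groups is None:
        groups = {"all": list(rpm_table.columns)}
    passing = pd.DataFrame(
        {name: log2t[cols].median(axis=1) >= threshold for name, cols in groups.items()}
    )
    keep = passing.all(axis=1) if require_all_groups else passing.any(axis=1)
    return list(rpm_table.index[keep])


def cellcount_ratio(records: pd.DataFrame) -> tuple[pd.DataFrame, TestResult | None]:
    """Per-animal receptor-positive / Orco-positive OSN ratios.

    ``records`` needs columns animal, species, or42a_positive,
    orco_positive.  Returns the table with a ``ratio`` column and, when
    exactly two species are present, a two-sided Mann-Whitney U
    comparison of the ratios.
    """
    req = {"animal", "species", "or42a_positive", "orco_positive"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (records["orco_positive"] <= 0).any():
        raise ValueError("orco_positive must be positive (total OSN count)")
    if (records["or42a_positive"] > records["orco_positive"]).any():
        raise ValueError("or42a_positive exceeds orco_positive")
    out = records.copy()
    out["ratio"] = out["or42a_positive"] / out["orco_positive"]
    species = sorted(out["species"].unique())
    test = None
    if len(species) == 2:
        a = out.loc[out["species"] == species[0], "ratio"]
        b = out.loc[out["species"] == species[1], "ratio"]
        test = mann_whitney_u(a, b, alternative="two-sided")
    return out, test
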