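"""Temporal DEMs: the direct 8 h-vs-3 h contrast among activated samples.

A temporal DEM (T-DEM) changes significantly between the two post-activation
time points. Phase is set by the sign of the 8 h-vs-3 h log2FC: negative
means expression was maximal at 3 h (``early``), positive means maximal at
8 h (``late``). The MA view (log2FC against mean log2-CPM over the activated
samples) is exported as a plain table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexp import Dispersion, nb_exact_test
from .prep import NormFactors

__all__ = ["temporal_contrast", "call_tdems", "ma_table"]


def activated_groups(design: pd.DataFrame, condition: str = "activated"):
    """Sample ids of the two activated time-point groups (3 h, 8 h)."""
    g3 = list(design.index[(design["condition"] == condition) & (design["timepoint"] == 3)])
    g8 = list(design.index[(design["condition"] == condition) & (design["timepoint"] == 8)])
    if not g3 or not g8:
        raise ValueError(f"condition {condition!r} needs samples at both 3 h and 8 h")
    return g3, g8


def temporal_contrast(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    dispersion: Dispersion | float,
    factors: NormFactors | None = None,
    condition: str = "activated",
) -> pd.DataFrame:
    """Exact test of 8 h vs 3 h using only the activated samples."""
    g3, g8 = activated_groups(design, condition)
    return nb_exact_test(counts, g3, g8, dispersion, factors=factors)


def call_tdems(
    de: pd.DataFrame, fdr_threshold: float = 0.05, fc_threshold: float = 0.33
) -> pd.DataFrame:
    """T-DEM records: significance and fold-change gates plus an early/late phase."""
    mask = (de["qvalue"] <= fdr_threshold) & (de["log2fc"].abs() > fc_threshold)
    tdems = de.loc[mask, ["log2fc", "avg_log2cpm", "qvalue"]].copy()
    tdems["phase"] = np.where(tdems["log2fc"] < 0, "early", "late")
    return tdems


def ma_table(de: pd.DataFrame, tdems: pd.DataFrame) -> pd.DataFrame:
    """All tested features with their T-DEM flag and phase, for MA plotting."""
    out = de[["log2fc", "avg_log2cpm", "qvalue"]].copy()
    out["tdem"] = out.index.isin(tdems.index)
    out["phase"] = tdems["phase"].reindex(out.index).fillna("")
    return out
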