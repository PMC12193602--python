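"""Nine-module temporal trend classification and abundance profiling.

Each feature gets a trend label at 3 h vs untreated and at 8 h vs 3 h:
``up`` if log2FC > threshold, ``down`` if log2FC < -threshold, else ``same``
(the default threshold 0.33 marks "same" as a change bounded by roughly a
quarter to a third on the linear scale). The two labels concatenate into one
of nine modules, e.g. ``up-down`` is a transient early wave and ``same-up``
a delayed response.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TREND_LABELS",
    "MODULE_NAMES",
    "assign_trend",
    "classify_modules",
    "summarize_modules",
    "abundance_profile",
]

TREND_LABELS = ("up", "same", "down")
MODULE_NAMES = tuple(f"{a}-{b}" for a in TREND_LABELS for b in TREND_LABELS)

DEFAULT_ABUNDANCE_EDGES = (10.0, 50.0, 100.0, 1000.0, 20000.0)


def assign_trend(log2fc, threshold: float = 0.33):
    """Trend label(s) for log2 fold change(s); boundary values are 'same'."""
    arr = np.asarray(log2fc, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("log2FC must not be NaN")
    labels = np.where(arr > threshold, "up", np.where(arr < -threshold, "down", "same"))
    if np.isscalar(log2fc) or arr.ndim == 0:
        return str(labels)
    return labels


def classify_modules(
    fc_3h_vs_nt: pd.Series, fc_8h_vs_3h: pd.Series, threshold: float = 0.33
) -> pd.DataFrame:
    """Assign every feature its two trend labels and nine-way module name.

    Both series must be indexed by feature id and cover the same features.
    """
    if not fc_3h_vs_nt.index.equals(fc_8h_vs_3h.index):
        missing = fc_3h_vs_nt.index.symmetric_difference(fc_8h_vs_3h.index)
        raise ValueError(f"fold changes missing for features: {list(missing)[:5]}")
    label_3h = assign_trend(fc_3h_vs_nt.to_numpy(), threshold)
    label_8h = assign_trend(fc_8h_vs_3h.to_numpy(), threshold)
    return pd.DataFrame(
        {
            "log2fc_3h": fc_3h_vs_nt,
            "log2fc_8h_vs_3h": fc_8h_vs_3h,
            "label_3h": label_3h,
            "label_8h": label_8h,
            "module": [f"{a}-{b}" for a, b in zip(label_3h, label_8h)],
        },
        index=fc_3h_vs_nt.index,
    )


def summarize_modules(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per module, all nine modules always present."""
    counts = assignments["module"].value_counts().reindex(MODULE_NAMES, fill_value=0)
    n = int(counts.sum())
    pct = counts / n * 100.0 if n else counts.astype(float)
    return pd.DataFrame({"count": counts.astype(int), "percent": pct})


def abundance_profile(
    mean_cpm: pd.Series, bin_edges=DEFAULT_ABUNDANCE_EDGES
) -> pd.DataFrame:
    """Feature counts per abundance stratum.

    Bins are half-open ``[lo, hi)`` starting at 0; the last bin is unbounded
    above. Default edges split at 10/50/100/1000/20000 CPM.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    cpm = mean_cpm.to_numpy(dtype=float)
    if (cpm < 0).any():
        raise ValueError("mean CPM must be nonnegative")
    full = np.concatenate(([0.0], edges, [np.inf]))
    counts, _ = np.histogram(cpm, bins=full)
    labels = [f"[{full[i]:g}, {full[i + 1]:g})" for i in range(len(full) - 1)]
    n = max(cpm.size, 1)
    return pd.DataFrame(
        {"count": counts, "percent": counts / n * 100.0}, index=labels
    )
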