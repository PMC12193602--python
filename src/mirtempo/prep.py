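"""Count-matrix preparation: validation, low-expression filtering, TMM and CPM.

The pipeline starts from a miRNA count matrix (features x samples, nonnegative
integers) and a sample design table. Normalization follows the standard
trimmed-mean-of-M-values (TMM) recipe: per-sample scaling factors are computed
from a doubly trimmed, precision-weighted mean of log2 count-fraction ratios
against a reference sample, then rescaled to geometric mean 1 so that the
effective library size is ``raw library size x factor``.

CPM convention used throughout the package::

    CPM(f, s) = count(f, s) * 1e6 / effective_library_size(s)

and log-CPM is ``log2(CPM + prior_cpm)`` with ``prior_cpm = 0.5`` by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CountFormatError",
    "NormFactors",
    "read_count_table",
    "write_count_table",
    "read_design_table",
    "validate_counts",
    "compute_cpm",
    "filter_low_expression",
    "tmm_factors",
    "pca_qc",
]

CONDITIONS = ("NT", "activated", "activated_drug")


class CountFormatError(ValueError):
    """Raised when a count table violates the format contract."""


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM factors and effective library sizes.

    Attributes
    ----------
    lib_size : pd.Series
        Raw library size (column sum) per sample.
    factor : pd.Series
        TMM scaling factor per sample; geometric mean is 1.
    """

    lib_size: pd.Series
    factor: pd.Series

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.factor

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lib_size": self.lib_size,
                "tmm_factor": self.factor,
                "effective_lib_size": self.effective_lib_size,
            }
        )

    @classmethod
    def unit(cls, counts: pd.DataFrame) -> "NormFactors":
        """Factors of 1 for every sample (library-size-only normalization)."""
        lib = counts.sum(axis=0).astype(float)
        return cls(lib_size=lib, factor=pd.Series(1.0, index=counts.columns))


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a features-x-samples count matrix and return it as int64.

    Raises :class:`CountFormatError` on duplicate feature/sample ids,
    negative or non-integer entries, or an all-zero matrix.
    """
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise CountFormatError(f"duplicate feature id: {dup!r}")
    if counts.columns.duplicated().any():
        dup = counts.columns[counts.columns.duplicated()][0]
        raise CountFormatError(f"duplicate sample id: {dup!r}")
    values = counts.to_numpy()
    if values.size == 0:
        raise CountFormatError("empty count matrix")
    if not np.issubdtype(values.dtype, np.number):
        raise CountFormatError("non-numeric entries in count matrix")
    if np.isnan(values.astype(float)).any():
        raise CountFormatError("missing values in count matrix")
    if (values < 0).any():
        raise CountFormatError("negative count")
    if not np.allclose(values, np.round(values.astype(float))):
        raise CountFormatError("non-integer count")
    out = counts.astype(np.int64)
    if not (out.to_numpy().sum(axis=0) > 0).any():
        raise CountFormatError("all samples have zero total count")
    return out


def read_count_table(path) -> pd.DataFrame:
    """Read a TSV count table (first column feature id, header of sample ids)."""
    try:
        counts = pd.read_csv(path, sep="\t", index_col=0)
    except (ValueError, pd.errors.ParserError) as exc:
        raise CountFormatError(f"malformed count table {path}: {exc}") from exc
    if counts.isna().to_numpy().any():
        raise CountFormatError(f"ragged or incomplete rows in {path}")
    try:
        return validate_counts(counts)
    except CountFormatError as exc:
        raise CountFormatError(f"{path}: {exc}") from exc


def write_count_table(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_design_table(path) -> pd.DataFrame:
    """Read a sample design TSV (sample_id, condition, timepoint, replicate)."""
    design = pd.read_csv(path, sep="\t", index_col="sample_id")
    bad = set(design["condition"]) - set(CONDITIONS)
    if bad:
        raise CountFormatError(f"unknown condition labels: {sorted(bad)}")
    design["timepoint"] = design["timepoint"].astype(int)
    return design


def compute_cpm(
    counts: pd.DataFrame,
    factors: NormFactors | None = None,
    prior_count: float = 0.0,
) -> pd.DataFrame:
    """Counts per million against effective library sizes.

    ``prior_count`` is added to every count before scaling (used only where a
    caller wants strictly positive CPM; the package default is 0 and log-CPM
    adds its prior on the CPM scale instead).
    """
    if factors is None:
        factors = NormFactors.unit(counts)
    eff = factors.effective_lib_size.reindex(counts.columns)
    if eff.isna().any():
        missing = list(counts.columns[eff.isna()])
        raise ValueError(f"normalization factors missing for samples: {missing}")
    if (eff <= 0).any():
        raise ValueError("zero or negative effective library size")
    return (counts + prior_count) * 1e6 / eff


def filter_low_expression(
    counts: pd.DataFrame, min_cpm: float = 4.0, min_samples: int = 3
) -> pd.DataFrame:
    """Keep features with CPM strictly above ``min_cpm`` in >= ``min_samples`` samples.

    CPM is computed against raw library sizes (factor 1): the filter is applied
    before normalization, and TMM factors are then computed on the retained
    features.
    """
    if min_samples > counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {counts.shape[1]} available samples"
        )
    lib = counts.sum(axis=0).astype(float)
    # a sample emptied by earlier filtering contributes no CPM evidence
    cpm = counts / lib.replace(0.0, np.nan) * 1e6
    keep = (cpm > min_cpm).fillna(False).sum(axis=1) >= min_samples
    return counts.loc[keep]


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float,
    trim_a: float,
) -> float:
    """TMM factor of one sample against the reference (both raw count vectors)."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        raise ValueError("sample shares no nonzero features with the reference")
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    reference: str | None = None,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean across samples (ties broken by input order), unless
    ``reference`` names a sample explicitly. Only features nonzero in both the
    sample and the reference enter the trimmed mean; M-values are trimmed by
    ``trim_m`` on each side and A-values by ``trim_a``; the retained M-values
    are weighted by their inverse asymptotic (delta-method) variance. Factors
    are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    values = counts.to_numpy(dtype=float)
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have a nonzero total count")
    if reference is None:
        f75 = np.quantile(values / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref_idx = counts.columns.get_loc(reference)
    ref = values[:, ref_idx]
    raw = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair_factor(values[:, j], ref, trim_m, trim_a)
            for j in range(values.shape[1])
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    return NormFactors(
        lib_size=pd.Series(lib, index=counts.columns),
        factor=pd.Series(factors, index=counts.columns),
    )


def pca_qc(
    cpm: pd.DataFrame,
    design: pd.DataFrame | None = None,
    n_components: int = 5,
    prior_cpm: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Unsupervised QC: sample coordinates on leading principal components.

    log2(CPM + prior) values are centered per feature and decomposed by SVD.
    Returns ``(scores, variance_fractions)`` where ``scores`` has one row per
    sample (columns ``PC1..PCk``) joined with the design when given, and
    ``variance_fractions`` are the non-increasing explained-variance ratios.
    """
    if cpm.shape[0] < 2:
        raise ValueError("PCA QC needs at least two features")
    if cpm.shape[1] < 3:
        raise ValueError("PCA QC needs at least three samples")
    x = np.log2(cpm.to_numpy(dtype=float) + prior_cpm)
    x = x - x.mean(axis=1, keepdims=True)
    # samples as observations
    u, s, vt = np.linalg.svd(x.T, full_matrices=False)
    k = min(n_components, s.size)
    coords = u[:, :k] * s[:k]
    var_frac = (s**2) / np.sum(s**2)
    scores = pd.DataFrame(
        coords, index=cpm.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    if design is not None:
        scores = scores.join(design)
    return scores, var_frac[:k]
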