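"""Unsupervised filtering and normalization of miRNA-seq count matrices.

The pipeline mirrors the standard small-RNA-seq preprocessing used for
prognostic-signature work: (1) drop miRNAs whose third quartile across
samples is below a count threshold, (2) drop samples whose median or first
quartile across the remaining miRNAs is exactly zero, (3) compute TMM
(trimmed mean of M-values) scaling factors, (4) convert to log2
counts-per-million with effective library sizes, and (5) apply the Blom
rank-based inverse-normal transformation per miRNA across samples.

Quantiles use linear interpolation of order statistics (the numpy default)
throughout, for both filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "filter_mirnas",
    "filter_samples",
    "tmm_normalization_factors",
    "normalize_counts",
    "blom_transform",
    "blom_from_reference",
    "fold_normalization",
    "preprocess_counts",
]


@dataclass
class CountMatrix:
    """Raw integer miRNA-seq counts, features (miRNAs) x samples."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.shape[1] == 0:
            raise ValueError("count matrix needs at least one sample")
        arr = df.to_numpy()
        if np.any(arr < 0):
            raise ValueError("count matrix contains negative entries")
        if df.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if df.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="mirna_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)


@dataclass
class ExpressionMatrix:
    """Normalized + Blom-transformed expression, features x samples."""

    values: pd.DataFrame
    normalization_factors: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.normalization_factors.to_numpy() <= 0):
            raise ValueError("normalization factors must be positive")

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="mirna_id",
                           float_format="%.6g")


def filter_mirnas(counts: CountMatrix, q3_threshold: float = 5) -> CountMatrix:
    """Keep miRNAs whose third quartile across samples is >= ``q3_threshold``.

    A miRNA with third quartile *fewer than* the threshold is excluded, so
    a feature sitting exactly at the threshold is retained. Feature order
    is preserved.
    """
    arr = counts.values.to_numpy(dtype=float)
    q3 = np.quantile(arr, 0.75, axis=1)
    keep = q3 >= q3_threshold
    if not keep.any():
        warnings.warn("all miRNAs removed by the Q3 filter")
    return CountMatrix(counts.values.loc[keep])


def filter_samples(counts: CountMatrix) -> CountMatrix:
    """Drop samples whose across-miRNA median or first quartile is exactly 0.

    Meant to run after :func:`filter_mirnas`, matching the pipeline order
    (miRNAs first, then samples).
    """
    arr = counts.values.to_numpy(dtype=float)
    med = np.quantile(arr, 0.5, axis=0)
    q1 = np.quantile(arr, 0.25, axis=0)
    keep = ~((med == 0) | (q1 == 0))
    if not keep.any():
        diag = pd.DataFrame({"median": med, "q1": q1}, index=counts.sample_ids)
        raise ValueError(f"all samples removed by the median/Q1 filter:\n{diag}")
    return CountMatrix(counts.values.loc[:, keep])


def _tmm_reference_column(arr: np.ndarray) -> int:
    # column whose 75th percentile of counts (scaled by library size) is
    # closest to the mean across columns
    lib = arr.sum(axis=0)
    f75 = np.quantile(arr, 0.75, axis=0) / lib
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray,
                     lib_obs: float, lib_ref: float,
                     logratio_trim: float, abs_trim: float) -> float:
    # M/A statistics on features positive in both samples
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
        w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    ok = np.isfinite(m) & np.isfinite(a) & (a > -1e10)
    m, a, w = m[ok], a[ok], w[ok]
    if m.size == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * abs_trim) + 1
    hi_s = n + 1 - lo_s
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def _raw_tmm_factors(arr: np.ndarray, ref_idx: int, logratio_trim: float,
                     abs_trim: float) -> np.ndarray:
    lib = arr.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("sample with zero library size")
    ref = arr[:, ref_idx]
    return np.array([
        _tmm_pair_factor(arr[:, j], ref, lib[j], lib[ref_idx],
                         logratio_trim, abs_trim)
        for j in range(arr.shape[1])
    ])


def tmm_normalization_factors(counts: CountMatrix,
                              logratio_trim: float = 0.3,
                              abs_trim: float = 0.05) -> pd.Series:
    """TMM scaling factors per sample, geometric mean rescaled to 1.

    Weighted trimmed mean of the M-values (log2 relative-abundance ratios)
    against a reference sample, with inverse asymptotic-variance weights;
    30% two-sided trim on M and 5% on the A (average abundance) scale by
    default. Features with a zero count in either compared sample are
    excluded pairwise.
    """
    arr = counts.values.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    if np.any(lib == 0):
        bad = [s for s, l in zip(counts.sample_ids, lib) if l == 0]
        raise ValueError(f"samples with zero library size: {bad}")
    ref_idx = _tmm_reference_column(arr)
    factors = _raw_tmm_factors(arr, ref_idx, logratio_trim, abs_trim)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def normalize_counts(counts: CountMatrix, factors: pd.Series,
                     pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on effective library sizes.

    Effective library size = raw library size x TMM factor; a fixed
    pseudocount (0.5) keeps zero counts finite at the CPM floor.
    """
    arr = counts.values.to_numpy(dtype=float)
    lib = arr.sum(axis=0)
    eff = lib * factors.reindex(counts.sample_ids).to_numpy()
    cpm = (arr + pseudocount) / (eff + 1.0)[None, :] * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.feature_ids,
                        columns=counts.sample_ids)


def blom_transform(values: np.ndarray, offset_c: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse-normal scores of a vector.

    Returns ``ndtri((r - c) / (n - 2c + 1))`` with tie-averaged ranks r and
    c = 3/8. A constant vector maps to all zeros (average rank (n+1)/2).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("Blom transform requires at least two observations")
    r = rankdata(x)
    return ndtri((r - offset_c) / (n - 2.0 * offset_c + 1.0))


def blom_from_reference(train_values: np.ndarray, new_values: np.ndarray,
                        offset_c: float = 3.0 / 8.0) -> np.ndarray:
    """Blom scores of new observations against a reference sample.

    Each new value is midranked within the reference vector (size m) and
    mapped through ``ndtri((r - c) / (m - 2c + 1))``; the new values do
    not influence each other. Used by the leak-free within-training-fold
    normalization mode to score held-out samples on the training scale.
    """
    v = np.sort(np.asarray(train_values, dtype=float))
    m = v.size
    x = np.asarray(new_values, dtype=float)
    below = np.searchsorted(v, x, side="left")
    ties = np.searchsorted(v, x, side="right") - below
    r = below + 0.5 * ties + 0.5
    return ndtri((r - offset_c) / (m - 2.0 * offset_c + 1.0))


def fold_normalization(train: CountMatrix, test: CountMatrix,
                       logratio_trim: float = 0.3, abs_trim: float = 0.05,
                       pseudocount: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TMM + log-CPM + Blom with all data-dependent choices from ``train``.

    The TMM reference column and the rescaling constant come from the
    training samples alone; held-out samples get pairwise factors against
    that same reference and Blom scores mapped through the training
    distribution of each miRNA. Returns (train, test) expression frames
    (samples never mix across the split).
    """
    if train.feature_ids != test.feature_ids:
        raise ValueError("train/test matrices must share features")
    tr = train.values.to_numpy(dtype=float)
    te = test.values.to_numpy(dtype=float)
    ref_idx = _tmm_reference_column(tr)
    raw_tr = _raw_tmm_factors(tr, ref_idx, logratio_trim, abs_trim)
    geo = np.exp(np.mean(np.log(raw_tr)))
    f_tr = pd.Series(raw_tr / geo, index=train.sample_ids)
    joint = np.column_stack([te, tr[:, ref_idx]])
    raw_te = _raw_tmm_factors(joint, joint.shape[1] - 1, logratio_trim, abs_trim)[:-1]
    f_te = pd.Series(raw_te / geo, index=test.sample_ids)
    logcpm_tr = normalize_counts(train, f_tr, pseudocount).to_numpy()
    logcpm_te = normalize_counts(test, f_te, pseudocount).to_numpy()
    expr_tr = np.apply_along_axis(blom_transform, 1, logcpm_tr)
    expr_te = np.empty_like(logcpm_te)
    for i in range(logcpm_tr.shape[0]):
        expr_te[i] = blom_from_reference(logcpm_tr[i], logcpm_te[i])
    return (pd.DataFrame(expr_tr, index=train.feature_ids, columns=train.sample_ids),
            pd.DataFrame(expr_te, index=test.feature_ids, columns=test.sample_ids))


def preprocess_counts(counts: CountMatrix, q3_threshold: float = 5,
                      logratio_trim: float = 0.3, abs_trim: float = 0.05,
                      pseudocount: float = 0.5) -> ExpressionMatrix:
    """Full preprocessing: filters, TMM, log2-CPM, per-miRNA Blom scores."""
    n_feat0, n_samp0 = counts.shape
    kept_f = filter_mirnas(counts, q3_threshold=q3_threshold)
    kept = filter_samples(kept_f)
    factors = tmm_normalization_factors(kept, logratio_trim, abs_trim)
    logcpm = normalize_counts(kept, factors, pseudocount=pseudocount)
    transformed = np.apply_along_axis(blom_transform, 1, logcpm.to_numpy())
    values = pd.DataFrame(transformed, index=logcpm.index, columns=logcpm.columns)
    provenance: Mapping = {
        "q3_threshold": q3_threshold,
        "logratio_trim": logratio_trim,
        "abs_trim": abs_trim,
        "pseudocount": pseudocount,
        "quantile_convention": "linear interpolation of order statistics",
        "n_mirnas_in": n_feat0,
        "n_mirnas_retained": kept.shape[0],
        "n_samples_in": n_samp0,
        "n_samples_retained": kept.shape[1],
    }
    return ExpressionMatrix(values, factors, dict(provenance))
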