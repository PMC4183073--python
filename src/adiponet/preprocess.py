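"""Count filtering, normalization and network-stage gene selection.

The pipeline order is fixed: low-count filter -> median-of-ratios size
factors -> offset log2-CPM with gender residualization -> SD filter ->
per-group connectivity-based selection.  Downstream stages consume only
correlations, so the normalization deliberately stops at covariate-corrected
log2-CPM: precision weights would not change any correlation-based result.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.stats import gmean
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "filter_low_expression",
    "size_factors",
    "normalize",
    "variance_filter",
    "select_by_connectivity",
    "CountNormalizer",
]


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValueError("duplicate gene or sample ids in count matrix")
    vals = counts.to_numpy()
    if vals.size and ((vals < 0).any() or not np.allclose(vals, np.round(vals))):
        raise ValueError("counts must be non-negative integers")


def filter_low_expression(counts: pd.DataFrame, threshold: float = 5) -> pd.DataFrame:
    """Drop genes whose mean raw count across samples is <= ``threshold``.

    Low-count genes are unreliable at both the counting and the correlation
    stage; the retained gene order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    _check_counts(counts)
    if counts.empty:
        warnings.warn("empty count matrix passed to filter_low_expression")
        return counts
    keep = counts.mean(axis=1) > threshold
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors, rescaled to geometric mean 1.

    For each sample j, ``s_j`` is the median over reference genes (genes with
    strictly positive counts in every sample) of ``k_ij / geomean_i``.  The
    returned factors satisfy ``gmean(s) == 1``.
    """
    _check_counts(counts)
    ref = counts.loc[(counts > 0).all(axis=1)]
    if ref.empty:
        raise ValueError(
            "size-factor estimation needs at least one gene with strictly "
            "positive counts in all samples"
        )
    gm = gmean(ref.to_numpy(), axis=1)
    ratios = ref.to_numpy() / gm[:, None]
    s = np.median(ratios, axis=0)
    s = s / gmean(s)
    return pd.Series(s, index=counts.columns, name="size_factor")


def normalize(
    counts: pd.DataFrame,
    sf: pd.Series,
    covariates: pd.DataFrame | None = None,
    gender_col: str = "gender",
) -> pd.DataFrame:
    """Offset log2-CPM on size-factor-corrected libraries, gender-corrected.

    ``value = log2((k/s_j + 0.5) / (L_j / 1e6))`` with ``L_j`` the corrected
    library size ``sum_i k_ij / s_j``.  If ``covariates`` is given, each gene
    is residualized on the gender indicator and the gene's grand mean is
    added back, so gender-group means become equal while the expression level
    stays interpretable.  The residualization is idempotent.
    """
    _check_counts(counts)
    if not sf.index.equals(counts.columns):
        sf = sf.reindex(counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("size factors must be positive and cover every sample")
    corrected = counts.to_numpy() / sf.to_numpy()[None, :]
    lib = corrected.sum(axis=0)
    expr = np.log2((corrected + 0.5) / (lib[None, :] / 1e6))
    expr = pd.DataFrame(expr, index=counts.index, columns=counts.columns)
    if covariates is None:
        return expr
    if gender_col not in covariates.columns:
        raise ValueError(f"covariates lack required column {gender_col!r}")
    gender = covariates.loc[counts.columns, gender_col]
    if gender.isna().any():
        raise ValueError("missing gender value for at least one sample")
    grand = expr.mean(axis=1)
    out = expr.copy()
    for level in gender.unique():
        cols = gender.index[gender == level]
        out[cols] = expr[cols].sub(expr[cols].mean(axis=1), axis=0)
    return out.add(grand, axis=0)


def variance_filter(expr: pd.DataFrame, sd_min: float) -> pd.DataFrame:
    """Keep genes with sample standard deviation (ddof=1) strictly > sd_min."""
    sd = expr.std(axis=1, ddof=1)
    return expr.loc[sd > sd_min]


def _group_connectivity(expr: np.ndarray, beta: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(expr)
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj.sum(axis=0) - 1.0


def select_by_connectivity(
    expr: pd.DataFrame,
    groups: pd.Series,
    top_n: int = 1500,
    beta: int = 7,
) -> list[str]:
    """Union of the ``top_n`` most connected genes within each group.

    Connectivity is computed per group on the group's samples only, using an
    unsigned adjacency at soft power ``beta``.  Ties break by (connectivity
    descending, gene id ascending); the returned union is sorted by gene id.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    groups = groups.loc[expr.columns]
    selected: set[str] = set()
    for g in sorted(groups.unique()):
        cols = groups.index[groups == g]
        if len(cols) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        k = _group_connectivity(expr[cols].to_numpy(), beta)
        order = sorted(zip(expr.index, k), key=lambda t: (-t[1], t[0]))
        n = top_n
        if top_n > len(order):
            warnings.warn(f"top_n={top_n} exceeds gene count {len(order)}; taking all")
            n = len(order)
        selected.update(gene for gene, _ in order[:n])
    return sorted(selected)


class CountNormalizer(BaseEstimator, TransformerMixin):
    """Transformer bundling low-count filtering, size factors and log2-CPM.

    Parameters
    ----------
    low_count_threshold : float
        Genes with mean raw count <= this are dropped at fit time.
    sd_min : float or None
        If set, genes with post-normalization SD <= sd_min are dropped.

    Attributes
    ----------
    size_factors_ : pd.Series
        Per-sample median-of-ratios factors, geometric mean 1.
    genes_ : pd.Index
        Genes surviving the filters, in input order.
    """

    def __init__(self, low_count_threshold: float = 5, sd_min: float | None = None):
        self.low_count_threshold = low_count_threshold
        self.sd_min = sd_min

    def fit(self, X: pd.DataFrame, y=None, *, covariates: pd.DataFrame | None = None):
        filtered = filter_low_expression(X, self.low_count_threshold)
        self.size_factors_ = size_factors(filtered)
        expr = normalize(filtered, self.size_factors_, covariates)
        if self.sd_min is not None:
            expr = variance_filter(expr, self.sd_min)
        self.genes_ = expr.index
        self._covariates = covariates
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        expr = normalize(X.loc[self.genes_], self.size_factors_, self._covariates)
        return expr

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)
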