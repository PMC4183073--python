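"""Module eigengenes, module-trait relationships, kME and gene-trait stats.

The eigengene of a module is the first right-singular vector of the module's
standardized genes x samples submatrix — the sample profile capturing the
largest share of the module's expression variance.  Its sign is fixed by
requiring a non-negative correlation with the module's mean standardized
expression, so module-trait correlation signs are reproducible.
Intra-modular connectivity is measured as kME, the correlation of a gene's
profile with a module eigengene; the classical sum-of-adjacency variant is
available as a diagnostic.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .network import UNASSIGNED

__all__ = [
    "eigengene",
    "module_eigengenes",
    "module_trait",
    "module_membership",
    "gene_trait_correlation",
    "select_modules",
    "refine_module",
    "intramodular_adjacency_connectivity",
    "MTRResult",
    "ModuleEigengenes",
]


class MTRResult(NamedTuple):
    """Module-trait relationships: Pearson r and two-sided p per pair."""

    r: pd.DataFrame
    p: pd.DataFrame


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene in module submatrix")
    return (x - mu) / sd


def eigengene(expr_module: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of a module and its variance explained.

    Returns the unit-norm eigengene (one value per sample) oriented to
    correlate non-negatively with the module's mean standardized expression,
    and ``var_explained = s1^2 / sum(s^2)`` of the standardized submatrix.
    """
    if expr_module.shape[0] < 2 or expr_module.shape[1] < 3:
        raise ValueError("eigengene needs >= 2 genes and >= 3 samples")
    z = _standardize_rows(expr_module.to_numpy())
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if s[0] == 0:
        raise ValueError("rank-0 module submatrix")
    e = vt[0]
    if np.dot(e, z.mean(axis=0)) < 0:
        e = -e
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return pd.Series(e, index=expr_module.columns, name="eigengene"), var_explained


def module_eigengenes(
    expr: pd.DataFrame, modules: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes (samples x modules) and variance explained per module.

    The grey/unassigned label is skipped.  Module columns are ordered by
    decreasing module size, ties by label.
    """
    modules = modules.loc[expr.index]
    names = [
        m
        for m in sorted(
            modules[modules != UNASSIGNED].unique(),
            key=lambda m: (-(modules == m).sum(), m),
        )
    ]
    cols, ve = {}, {}
    for m in names:
        e, v = eigengene(expr.loc[modules[modules == m].index])
        cols[m] = e
        ve[m] = v
    eig = pd.DataFrame(cols, index=expr.columns)
    return eig, pd.Series(ve, name="var_explained")


def module_trait(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> MTRResult:
    """Pearson correlation and two-sided p-value per (module, trait).

    p-values are asymptotic Student-t with n-2 degrees of freedom, reported
    raw (no multiple-testing correction across the matrix).
    """
    if eigengenes.shape[0] < 4:
        raise ValueError("module-trait correlation needs >= 4 samples")
    traits = traits.loc[eigengenes.index]
    if traits.isna().any().any():
        raise ValueError("traits contain missing values")
    for t in traits.columns:
        if traits[t].std(ddof=1) == 0:
            raise ValueError(f"constant trait {t!r}")
    r = pd.DataFrame(index=eigengenes.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    for m in eigengenes.columns:
        for t in traits.columns:
            res = stats.pearsonr(eigengenes[m], traits[t])
            r.loc[m, t] = res.statistic
            p.loc[m, t] = res.pvalue
    return MTRResult(r=r, p=p)


def _cor_rows_cols(rows: pd.DataFrame, cols: pd.DataFrame) -> pd.DataFrame:
    """Correlation of every row of ``rows`` with every column of ``cols``."""
    x = _standardize_rows(rows.to_numpy())
    y = _standardize_rows(cols.to_numpy().T)
    r = x @ y.T / (x.shape[1] - 1)
    return pd.DataFrame(np.clip(r, -1, 1), index=rows.index, columns=cols.columns)


def module_membership(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME: correlation of each gene with each module eigengene."""
    return _cor_rows_cols(expr, eigengenes)


def gene_trait_correlation(expr: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """GS: correlation of each gene's profile with each trait."""
    return _cor_rows_cols(expr, traits.loc[expr.columns])


def select_modules(mtr: MTRResult | pd.DataFrame, threshold: float = 0.5) -> list[str]:
    """Modules whose strongest trait correlation exceeds ``threshold`` (strict)."""
    r = mtr.r if isinstance(mtr, MTRResult) else mtr
    strongest = r.abs().max(axis=1)
    return list(strongest.index[strongest > threshold])


def refine_module(
    kme: pd.DataFrame,
    module: str,
    own_min: float = 0.6,
    other_max: float = 0.6,
) -> list[str]:
    """Genes retained in a module by the intra-modular connectivity rule.

    A gene stays when its kME with its own module exceeds ``own_min`` and its
    kME with every other module stays below ``other_max`` (both strict).  A
    stricter ``own_min`` (e.g. 0.9) reproduces hub-focused module reduction.
    """
    if module not in kme.columns:
        raise KeyError(f"unknown module {module!r}")
    own = kme[module]
    others = kme.drop(columns=module)
    ok = own > own_min
    if not others.empty:
        ok &= others.abs().max(axis=1) < other_max
    return list(kme.index[ok])


def intramodular_adjacency_connectivity(
    adj: pd.DataFrame, modules: pd.Series, module: str
) -> pd.Series:
    """Diagnostic: within-module sum-of-adjacency connectivity."""
    genes = modules.index[modules == module]
    sub = adj.loc[genes, genes].to_numpy()
    return pd.Series(sub.sum(axis=1) - np.diag(sub), index=genes, name="kIM")


class ModuleEigengenes(BaseEstimator, TransformerMixin):
    """Transformer mapping expression to module-eigengene sample scores.

    ``fit(X, y)`` takes a genes x samples matrix and per-gene module labels;
    ``transform`` projects samples onto the fitted eigengene directions,
    returning a samples x modules score matrix.
    """

    def fit(self, X: pd.DataFrame, y: pd.Series):
        X = pd.DataFrame(X)
        modules = pd.Series(y, index=X.index)
        self.eigengenes_, self.var_explained_ = module_eigengenes(X, modules)
        self._modules = modules
        self._train_genes = X.index
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).loc[self._train_genes]
        out = {}
        for m in self.eigengenes_.columns:
            genes = self._modules.index[self._modules == m]
            z = _standardize_rows(X.loc[genes].to_numpy())
            # project standardized genes onto the eigengene direction weights
            weights = z @ self.eigengenes_[m].to_numpy()
            e = weights @ z / np.linalg.norm(weights @ z)
            out[m] = e
        return pd.DataFrame(out, index=X.columns)
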