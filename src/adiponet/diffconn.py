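"""Lean vs obese differential connectivity.

Condition-specific sub-networks are built from each condition's samples only
(the intermediate group contributes nothing here), at a soft power of 9.
Each gene's connectivity is normalized by the sub-network maximum so values
lie in [0, 1]; the differential connectivity ``k_diff = k_obese - k_lean``
then lies in [-1, 1] and is antisymmetric under swapping the groups.  Genes
are called when both |k_diff| and the lean-vs-obese two-sample t statistic
exceed their thresholds.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import _group_connectivity

logger = logging.getLogger(__name__)

__all__ = [
    "subnetwork_connectivity",
    "k_diff",
    "group_t_stats",
    "differential_connectivity",
    "select_diff_genes",
]


def subnetwork_connectivity(
    expr: pd.DataFrame, samples, beta: int = 9
) -> pd.Series:
    """Max-normalized connectivity of the sub-network on ``samples``."""
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("sub-network needs at least 3 samples")
    k = _group_connectivity(expr[samples].to_numpy(), beta)
    kmax = k.max()
    if kmax == 0:
        raise ValueError("degenerate sub-network: all connectivities are zero")
    return pd.Series(k / kmax, index=expr.index, name="k_norm")


def k_diff(k_lean_norm: pd.Series, k_obese_norm: pd.Series) -> pd.Series:
    """Differential connectivity ``k_obese_norm - k_lean_norm`` per gene.

    Positive values mean the gene is more connected in the obese sub-network.
    """
    if not k_lean_norm.index.equals(k_obese_norm.index):
        raise ValueError("lean and obese connectivity indexes differ")
    return (k_obese_norm - k_lean_norm).rename("k_diff")


def group_t_stats(
    expr: pd.DataFrame,
    lean_samples,
    obese_samples,
    welch: bool = False,
) -> pd.Series:
    """Two-sample t statistic per gene, signed obese mean minus lean mean.

    Pooled-variance by default (the standard two-sample t-test); Welch's
    unequal-variance variant behind ``welch=True``.  A zero pooled variance
    with unequal means yields +-inf, which exceeds any finite threshold.
    """
    lean = expr[list(lean_samples)].to_numpy()
    obese = expr[list(obese_samples)].to_numpy()
    if lean.shape[1] < 2 or obese.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = stats.ttest_ind(obese, lean, axis=1, equal_var=not welch).statistic
    diff = obese.mean(axis=1) - lean.mean(axis=1)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.warning("%d genes with zero pooled variance; t set to signed inf/0",
                       int(degenerate.sum()))
        t = np.where(degenerate, np.sign(diff) * np.inf, t)
        t = np.where(degenerate & (diff == 0), 0.0, t)
    return pd.Series(t, index=expr.index, name="t_stat")


def differential_connectivity(
    expr: pd.DataFrame,
    groups: pd.Series,
    beta: int = 9,
    kd_threshold: float = 0.6,
    t_threshold: float = 1.96,
    welch: bool = False,
) -> pd.DataFrame:
    """Full differential-connectivity table for lean vs obese samples.

    ``groups`` maps sample id to group label; only "lean" and "obese"
    samples are used.  Returns per gene: k_lean_norm, k_obese_norm, k_diff,
    t_stat and the joint selection flag.
    """
    groups = groups.loc[[s for s in expr.columns if s in groups.index]]
    lean = list(groups.index[groups == "lean"])
    obese = list(groups.index[groups == "obese"])
    kl = subnetwork_connectivity(expr, lean, beta=beta)
    ko = subnetwork_connectivity(expr, obese, beta=beta)
    kd = k_diff(kl, ko)
    t = group_t_stats(expr, lean, obese, welch=welch)
    table = pd.DataFrame(
        {"k_lean_norm": kl, "k_obese_norm": ko, "k_diff": kd, "t_stat": t}
    )
    table["selected"] = (kd.abs() > kd_threshold) & (t.abs() > t_threshold)
    n_conn = int((kd.abs() > kd_threshold).sum())
    logger.info(
        "differentially connected: %d; also differentially expressed: %d",
        n_conn, int(table["selected"].sum()),
    )
    return table


def select_diff_genes(
    table: pd.DataFrame, kd_threshold: float = 0.6, t_threshold: float = 1.96
) -> list[str]:
    """Genes passing both absolute thresholds, by decreasing |k_diff|."""
    mask = (table["k_diff"].abs() > kd_threshold) & (table["t_stat"].abs() > t_threshold)
    hits = table.loc[mask]
    order = hits["k_diff"].abs().sort_values(ascending=False, kind="mergesort")
    return list(order.index)
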