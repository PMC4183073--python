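"""Gene-length-bias-corrected over-representation analysis.

Longer genes are detected (and hence selected) more readily in RNA-Seq, so a
plain hypergeometric enrichment test is biased.  The probability weighting
function (PWF) — a monotone estimate of P(selected | gene length), fitted by
isotonic regression — converts the bias into per-term odds for Wallenius'
noncentral hypergeometric distribution: a term whose genes are long gets
higher odds under the null and is penalized accordingly.  Raw p-values are
Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

__all__ = ["fit_pwf", "wallenius_test", "bh_adjust", "enrich_module"]

_CLIP = 1e-6


def fit_pwf(selected: pd.Series, lengths: pd.Series, n_bins: int = 10) -> pd.Series:
    """Probability weighting function: P(selected | length), isotonic in length.

    ``selected`` is a boolean flag per background gene; ``lengths`` gives the
    gene length in bp.  Genes are pooled into length-quantile bins and the
    per-bin selection proportions are fitted by isotonic regression weighted
    by bin size — fitting the raw 0/1 indicator would let the monotone fit
    chase single genes at the length extremes.  Weights are clipped to the
    open unit interval.
    """
    lengths = lengths.loc[selected.index].astype(float)
    y = selected.astype(float).to_numpy()
    n_sel = int(y.sum())
    if n_sel == 0 or n_sel == y.size:
        raise ValueError("PWF needs both selected and unselected genes")
    if n_sel < 10 or y.size - n_sel < 10:
        warnings.warn("fewer than 10 genes on one side of the selection flag; "
                      "the PWF will be unstable")
    bins = pd.qcut(lengths, q=min(n_bins, lengths.nunique()), duplicates="drop")
    grouped = pd.DataFrame({"y": y, "len": lengths}).groupby(bins, observed=True)
    rate = grouped["y"].mean()
    mean_len = grouped["len"].mean()
    size = grouped.size()
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(mean_len.to_numpy(), rate.to_numpy(), sample_weight=size.to_numpy())
    w = np.clip(iso.predict(lengths.to_numpy()), _CLIP, 1 - _CLIP)
    return pd.Series(w, index=selected.index, name="pwf")


def wallenius_test(
    term_genes, selected: pd.Series, pwf: pd.Series, background=None
) -> float:
    """Upper-tail Wallenius noncentral hypergeometric p for one term.

    The urn holds the background genes; term genes are the "successes" with
    odds ``omega = mean(pwf | term) / mean(pwf | not term)``; the number of
    draws is the number of selected genes and the observed count is
    ``|selected & term|``.  ``omega = 1`` reduces to the central
    hypergeometric test.
    """
    background = set(selected.index if background is None else background)
    term = set(term_genes) & background
    if not set(term_genes) <= background:
        raise ValueError("term contains genes outside the background")
    if not term:
        warnings.warn("empty term: p = 1")
        return 1.0
    sel = set(selected.index[selected])
    M = len(background)
    K = len(term)
    n = len(sel)
    x = len(sel & term)
    if x == 0:
        return 1.0
    term_idx = pwf.index.isin(term)
    mean_term = pwf.to_numpy()[term_idx].mean()
    nonterm = pwf.to_numpy()[~term_idx & pwf.index.isin(background)]
    omega = mean_term / nonterm.mean() if nonterm.size else 1.0
    if abs(omega - 1.0) < 1e-12:
        return float(hypergeom.sf(x - 1, M, K, n))
    return float(nchypergeom_wallenius.sf(x - 1, M, K, n, omega))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich_module(
    module_genes,
    background,
    gene_sets: dict[str, list[str]],
    lengths: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Length-bias-corrected over-representation table for one gene set.

    One row per term with at least one background gene: observed count,
    term size, Wallenius p and BH-adjusted p, with significance at
    ``p_adj < alpha``.  Sorted by raw p, ties by term id.
    """
    background = sorted(set(background))
    module = set(module_genes)
    if not module <= set(background):
        raise ValueError("module genes must be a subset of the background")
    if not module:
        warnings.warn("empty module: empty enrichment table")
        return pd.DataFrame(
            columns=["term", "n_selected_in_term", "n_term", "p", "p_adj", "significant"]
        ).set_index("term")
    selected = pd.Series([g in module for g in background], index=background)
    pwf = fit_pwf(selected, lengths)
    rows = []
    for term, genes in gene_sets.items():
        members = set(genes) & set(background)
        if not members:
            continue
        p = wallenius_test(members, selected, pwf, background)
        rows.append((term, len(members & module), len(members), p))
    table = pd.DataFrame(rows, columns=["term", "n_selected_in_term", "n_term", "p"])
    table["p_adj"] = bh_adjust(table["p"])
    table["significant"] = table["p_adj"] < alpha
    table = table.sort_values(["p", "term"], kind="mergesort").set_index("term")
    return table
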