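"""Module-network clustering and probabilistic regulator scoring.

A simplified module-network procedure: genes (centered and scaled) are
clustered by a Dirichlet-process Gibbs sampler under a per-(cluster, sample)
Gaussian model with a normal-gamma conjugate prior; the sampler is run
several times and runs are integrated into tight clusters (gene pairs
co-clustered in at least a threshold fraction of runs, connected components
of the resulting graph).  Each tight cluster defines a hierarchical sample
tree on its mean-expression profile; candidate regulator genes are assigned
to tree nodes by 1-D logistic regression of the node's left/right split on
the regulator's expression, scored by the -log10 likelihood-ratio p-value
weighted by the balance of the split, and summed over the ensemble into a
global probabilistic score.  High score <=> the regulator's expression
differs systematically between the two sides of cluster sample partitions.

The exact Bayesian scores of the published module-network software are
data- and implementation-specific; this module preserves the procedure's
testable behavior (tight clusters of a minimum size, split-differential
scoring, ensemble summation, top-percentile selection, random-set t-test)
with documented, simpler surrogates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import gammaln
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "GibbsSampleClusterer",
    "TightClusterEnsemble",
    "ClusterSet",
    "SampleTree",
    "RegulatorScores",
    "gibbs_cluster",
    "tight_clusters",
    "build_sample_tree",
    "score_regulator",
    "score_genes",
    "ensemble_regulator_scores",
    "top_regulators",
    "regulator_significance",
]

#: -log10 p is capped here so perfectly separating regulators stay comparable
SCORE_CAP = 16.0
#: a regulator is assigned to a node only when its association is nominally
#: significant; unassigned nodes contribute nothing to the ensemble sum
ASSIGN_ALPHA = 0.05


def _check_standardized(x: np.ndarray, tol: float = 1e-6) -> None:
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    if np.abs(mu).max() > tol or np.abs(sd - 1).max() > 100 * tol:
        raise ValueError(
            "expression must be centered and scaled per gene (mean 0, SD 1)"
        )


def standardize(expr: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Center and scale each gene to mean 0, SD 1."""
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    if (sd == 0).any():
        raise ValueError("cannot standardize a constant gene")
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


# ---------------------------------------------------------------------------
# Gibbs clustering
# ---------------------------------------------------------------------------

class GibbsSampleClusterer(BaseEstimator, ClusterMixin):
    """Dirichlet-process Gaussian mixture over genes, collapsed Gibbs sampling.

    Each cluster models every sample independently with a Gaussian whose
    mean and precision carry a normal-gamma prior (mu0, lambda0, a0, b0);
    gene reassignment probabilities are proportional to the cluster size
    (or the concentration ``alpha`` for a new cluster) times the Student-t
    posterior-predictive likelihood of the gene's profile.  The final-sweep
    assignment is returned.

    Input rows must be standardized (mean 0, SD 1 per gene).
    """

    def __init__(
        self,
        n_sweeps: int = 200,
        alpha: float = 1.0,
        mu0: float = 0.0,
        lambda0: float = 0.1,
        a0: float = 1.0,
        b0: float = 1.0,
        random_state: int | None = None,
    ):
        self.n_sweeps = n_sweeps
        self.alpha = alpha
        self.mu0 = mu0
        self.lambda0 = lambda0
        self.a0 = a0
        self.b0 = b0
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        genes = X.index
        x = X.to_numpy(dtype=float)
        _check_standardized(x)
        rng = np.random.default_rng(self.random_state)
        G, S = x.shape

        # start from singletons: coalescing into clusters through single-gene
        # moves mixes far better than trying to split one big cluster
        cap = G + 1
        n = np.zeros(cap)
        s1 = np.zeros((cap, S))
        s2 = np.zeros((cap, S))
        active: list[int] = list(range(G))
        assign = np.arange(G, dtype=int)
        n[:G] = 1.0
        s1[:G] = x
        s2[:G] = x**2

        lam0, a0, b0, mu0 = self.lambda0, self.a0, self.b0, self.mu0
        log_alpha = math.log(self.alpha)

        def log_pred(ids: list[int], xi: np.ndarray) -> np.ndarray:
            # posterior-predictive Student-t log-likelihood of profile xi
            # under each cluster in ids (with mu0 = 0 absorbed via shift)
            nn = n[ids][:, None]
            S1 = s1[ids] + lam0 * mu0
            lam_n = lam0 + nn
            mu_n = S1 / lam_n
            a_n = a0 + nn / 2.0
            b_n = b0 + 0.5 * (s2[ids] + lam0 * mu0**2) - 0.5 * S1**2 / lam_n
            nu = 2.0 * a_n
            sc2 = b_n * (lam_n + 1.0) / (a_n * lam_n)
            z2 = (xi[None, :] - mu_n) ** 2 / (nu * sc2)
            lp = (
                gammaln((nu + 1) / 2)
                - gammaln(nu / 2)
                - 0.5 * np.log(nu * np.pi * sc2)
                - (nu + 1) / 2 * np.log1p(z2)
            )
            return lp.sum(axis=1)

        free = list(range(cap - 1, 0, -1))
        for _ in range(self.n_sweeps):
            for g in range(G):
                c = assign[g]
                xi = x[g]
                n[c] -= 1
                s1[c] -= xi
                s2[c] -= xi**2
                if n[c] == 0:
                    active.remove(c)
                    free.append(c)
                new_id = free[-1]
                ids = active + [new_id]
                logw = log_pred(ids, xi)
                logw[: len(active)] += np.log(n[active])
                logw[-1] += log_alpha
                w = np.exp(logw - logw.max())
                w /= w.sum()
                pick = ids[int(np.searchsorted(np.cumsum(w), rng.random()))]
                if pick == new_id:
                    free.pop()
                    active.append(pick)
                assign[g] = pick
                n[pick] += 1
                s1[pick] += xi
                s2[pick] += xi**2

        # relabel clusters densely by size desc, first-seen order for ties
        order = sorted(set(assign), key=lambda c: (-(assign == c).sum(), c))
        remap = {c: i for i, c in enumerate(order)}
        self.labels_ = np.array([remap[c] for c in assign])
        self.assignments_ = pd.Series(self.labels_, index=genes, name="cluster")
        return self


def gibbs_cluster(
    expr: pd.DataFrame, n_sweeps: int = 200, seed: int | None = None, **kwargs
) -> pd.Series:
    """One Gibbs clustering run; returns the final-sweep gene -> cluster map."""
    model = GibbsSampleClusterer(n_sweeps=n_sweeps, random_state=seed, **kwargs)
    return model.fit(expr).assignments_


# ---------------------------------------------------------------------------
# tight clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Consensus clusters over repeated runs plus the co-clustering matrix."""

    clusters: dict[str, list[str]]
    coclustering: pd.DataFrame


def tight_clusters(
    runs: list[pd.Series],
    freq_threshold: float = 0.8,
    min_size: int = 10,
) -> ClusterSet:
    """Integrate clustering runs into a single robust solution.

    The co-clustering frequency of every gene pair is computed over the
    runs; pairs co-clustered in at least ``freq_threshold`` of runs form
    graph edges, and connected components with at least ``min_size`` genes
    become tight clusters (named C1, C2, ... by decreasing size).
    """
    if len(runs) < 2:
        raise ValueError("tight clustering needs at least 2 runs")
    genes = runs[0].index
    labels = np.stack([r.loc[genes].to_numpy() for r in runs])
    eq = (labels[:, :, None] == labels[:, None, :]).mean(axis=0)
    cocluster = pd.DataFrame(eq, index=genes, columns=genes)
    adj = csr_matrix(eq >= freq_threshold)
    n_comp, comp = connected_components(adj, directed=False)
    clusters = {}
    sizes = pd.Series(comp).value_counts()
    rank = 0
    for c in sorted(sizes.index, key=lambda c: (-sizes[c], c)):
        if sizes[c] < min_size:
            continue
        rank += 1
        clusters[f"C{rank}"] = list(genes[comp == c])
    return ClusterSet(clusters=clusters, coclustering=cocluster)


class TightClusterEnsemble(BaseEstimator, ClusterMixin):
    """Ensemble of Gibbs clustering runs integrated into tight clusters.

    Run ``r`` uses seed ``random_state + r`` so the ensemble is reproducible
    and each run is independent.  Genes outside every tight cluster get the
    label "unclustered".
    """

    def __init__(
        self,
        n_runs: int = 10,
        freq_threshold: float = 0.8,
        min_cluster_size: int = 10,
        n_sweeps: int = 200,
        alpha: float = 1.0,
        random_state: int = 0,
    ):
        self.n_runs = n_runs
        self.freq_threshold = freq_threshold
        self.min_cluster_size = min_cluster_size
        self.n_sweeps = n_sweeps
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        self.runs_ = [
            gibbs_cluster(
                X, n_sweeps=self.n_sweeps, seed=self.random_state + r, alpha=self.alpha
            )
            for r in range(self.n_runs)
        ]
        cs = tight_clusters(
            self.runs_, freq_threshold=self.freq_threshold, min_size=self.min_cluster_size
        )
        self.clusters_ = cs.clusters
        self.coclustering_ = cs.coclustering
        lab = pd.Series("unclustered", index=X.index, name="cluster")
        for name, genes in cs.clusters.items():
            lab.loc[genes] = name
        self.assignments_ = lab
        self.labels_ = lab.to_numpy()
        return self


# ---------------------------------------------------------------------------
# sample trees
# ---------------------------------------------------------------------------

@dataclass
class SampleTree:
    """Binary hierarchical partition of samples for one cluster.

    ``nodes`` lists internal nodes root-first as (left sample ids, right
    sample ids); a degenerate tree (all samples identical) has no nodes.
    """

    nodes: list[tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=list)
    degenerate: bool = False

    @property
    def root_split(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        if not self.nodes:
            raise ValueError("degenerate tree has no root split")
        return self.nodes[0]


def per_run_tree_collections(
    expr: pd.DataFrame, runs: list[pd.Series], min_size: int = 10
) -> list[dict[str, SampleTree]]:
    """One cluster -> SampleTree mapping per clustering run.

    Each run contributes trees for its own clusters of at least ``min_size``
    genes (named by size rank within the run).  Scoring the ensemble of
    per-run trees lets consistent regulator signal accumulate across runs
    while chance associations with any single tree's nodes stay isolated.
    """
    collections = []
    for run in runs:
        sizes = run.value_counts()
        big = [c for c in sorted(sizes.index, key=lambda c: (-sizes[c], c))
               if sizes[c] >= min_size]
        collections.append(
            {
                f"C{rank + 1}": build_sample_tree(expr.loc[run.index[run == c]])
                for rank, c in enumerate(big)
            }
        )
    return collections


def build_sample_tree(cluster_expr: pd.DataFrame) -> SampleTree:
    """Hierarchical sample tree on a cluster's mean-expression profile.

    Samples are merged by average-linkage Euclidean clustering of the
    per-sample mean over the cluster's genes; internal nodes are listed
    root-first, so ``nodes[0]`` is the partition defined by the first node.
    """
    samples = list(cluster_expr.columns)
    profile = cluster_expr.to_numpy().mean(axis=0)
    Z = linkage(profile[:, None], method="average", metric="euclidean")
    if Z[:, 2].max() == 0:
        warnings.warn("all samples identical for this cluster: degenerate tree")
        return SampleTree(nodes=[], degenerate=True)
    root = to_tree(Z)
    nodes = []
    queue = [root]
    while queue:
        node = queue.pop(0)
        if node.is_leaf():
            continue
        left = tuple(samples[i] for i in sorted(node.left.pre_order()))
        right = tuple(samples[i] for i in sorted(node.right.pre_order()))
        nodes.append((left, right))
        queue.extend([node.left, node.right])
    return SampleTree(nodes=nodes, degenerate=False)


# ---------------------------------------------------------------------------
# logistic node scores
# ---------------------------------------------------------------------------

def _logistic_lr_pvalues(x: np.ndarray, y: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """Likelihood-ratio p-values of the slope in 1-D logistic regressions.

    ``x`` is (n_regulators, n_samples) of standardized predictors, ``y`` a
    shared binary response.  Damped Newton iterations, batched across rows;
    fitted probabilities are clipped so separated fits plateau at a finite
    log-likelihood (the score cap makes the residual difference irrelevant).
    """
    R, n = x.shape
    y = y.astype(float)
    b = np.zeros((R, 2))
    for _ in range(n_iter):
        eta = b[:, :1] + b[:, 1:] * x
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(p * (1 - p), 1e-10, None)
        r = y[None, :] - p
        g0, g1 = r.sum(1), (r * x).sum(1)
        h00, h01, h11 = w.sum(1), (w * x).sum(1), (w * x * x).sum(1)
        det = h00 * h11 - h01**2 + 1e-12
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        step = np.clip(np.stack([db0, db1], axis=1), -5, 5)
        b += step
    eta = b[:, :1] + b[:, 1:] * x
    p = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35))), 1e-12, 1 - 1e-12)
    ll_full = (y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=1)
    pbar = y.mean()
    ll_null = n * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))
    lr = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    return stats.chi2.sf(lr, df=1)


def _node_scores(
    expr: pd.DataFrame,
    node: tuple[tuple[str, ...], tuple[str, ...]],
    cap: float = SCORE_CAP,
) -> pd.Series:
    left, right = node
    cols = list(left) + list(right)
    y = np.array([0.0] * len(left) + [1.0] * len(right))
    x = expr[cols].to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    scores = np.zeros(len(expr))
    if ok.any():
        z = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok]
        pv = _logistic_lr_pvalues(z, y)
        with np.errstate(divide="ignore"):
            raw = np.minimum(-np.log10(np.maximum(pv, 1e-300)), cap)
        raw[pv >= ASSIGN_ALPHA] = 0.0  # not assigned to this node
        weight = min(len(left), len(right)) / len(cols)
        scores[ok] = weight * raw
    return pd.Series(scores, index=expr.index)


def score_regulator(regulator_expr: pd.Series, node, cap: float = SCORE_CAP) -> float:
    """Node score of one regulator: balance-weighted -log10 LR p-value.

    Zero for a constant regulator; capped for perfectly separating ones.
    """
    if not node[0] or not node[1]:
        raise ValueError("node sides must be non-empty")
    df = regulator_expr.to_frame().T
    return float(_node_scores(df, node, cap=cap).iloc[0])


def score_genes(
    expr: pd.DataFrame,
    tree: SampleTree,
    min_side: int = 5,
    max_nodes: int = 3,
    cap: float = SCORE_CAP,
) -> pd.Series:
    """Sum of node scores of every gene against one cluster's sample tree.

    Only the first ``max_nodes`` internal nodes (root-first) whose smaller
    side has at least ``min_side`` samples are scored.
    """
    total = pd.Series(0.0, index=expr.index)
    scored = 0
    for node in tree.nodes:
        if min(len(node[0]), len(node[1])) < min_side:
            continue
        total += _node_scores(expr, node, cap=cap)
        scored += 1
        if scored >= max_nodes:
            break
    return total


# ---------------------------------------------------------------------------
# ensemble scores, selection, significance
# ---------------------------------------------------------------------------

class RegulatorScores(NamedTuple):
    per_cluster: pd.DataFrame  # regulators x clusters
    global_score: pd.Series


def ensemble_regulator_scores(
    expr: pd.DataFrame,
    regulators: list[str],
    tree_collections: list[dict[str, SampleTree]],
    min_side: int = 5,
    max_nodes: int = 3,
) -> RegulatorScores:
    """Probabilistic regulator scores summed over the tree ensemble.

    ``tree_collections`` holds one cluster -> SampleTree mapping per
    ensemble member (e.g. per clustering run); scores are additive over
    members, clusters and nodes.  Regulators absent from ``expr`` are
    skipped with a warning.
    """
    present = [r for r in regulators if r in expr.index]
    missing = sorted(set(regulators) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} candidate regulators absent from the "
                      f"expression matrix were skipped (e.g. {missing[0]})")
    reg_expr = expr.loc[present]
    cluster_names = sorted({c for coll in tree_collections for c in coll})
    per = pd.DataFrame(0.0, index=present, columns=cluster_names)
    for coll in tree_collections:
        for cname, tree in coll.items():
            per[cname] += score_genes(reg_expr, tree, min_side=min_side, max_nodes=max_nodes)
    return RegulatorScores(per_cluster=per, global_score=per.sum(axis=1).rename("global_score"))


def top_regulators(global_scores: pd.Series, pct: float = 0.01) -> list[str]:
    """Top ``ceil(pct * n)`` regulators by global score, ties broken by id."""
    if not 0 < pct <= 1:
        raise ValueError("pct must lie in (0, 1]")
    n = math.ceil(pct * len(global_scores))
    order = sorted(global_scores.items(), key=lambda t: (-t[1], t[0]))
    return [g for g, _ in order[:n]]


class SignificanceResult(NamedTuple):
    t_stat: float
    p_value: float


def regulator_significance(
    expr: pd.DataFrame,
    tree_collections: list[dict[str, SampleTree]],
    assigned: list[str],
    candidates: list[str],
    n_random: int = 100,
    seed: int | None = None,
    scores: pd.Series | None = None,
    **score_kwargs,
) -> SignificanceResult:
    """t-test of assigned-regulator scores against randomly assigned genes.

    ``n_random`` gene sets of the same size as ``assigned`` are drawn from
    genes that are not candidate regulators, scored identically, and the two
    score samples are compared with a two-sample t-test.  Precomputed global
    scores covering the assigned genes and the non-candidate pool may be
    passed via ``scores`` to avoid rescoring.
    """
    if len(assigned) < 2:
        raise ValueError("need at least 2 assigned regulators")
    pool = [g for g in expr.index if g not in set(candidates)]
    if len(pool) < len(assigned):
        raise ValueError("not enough non-candidate genes to draw random sets")
    rng = np.random.default_rng(seed)
    if scores is None:
        # per-gene scores are independent: score the pool once and sample
        scores = ensemble_regulator_scores(
            expr, list(assigned) + pool, tree_collections, **score_kwargs
        ).global_score
    assigned_scores = scores.loc[list(assigned)].to_numpy()
    random_scores = np.concatenate(
        [
            scores.loc[[pool[i] for i in rng.choice(len(pool), len(assigned), replace=False)]]
            for _ in range(n_random)
        ]
    )
    t, p = stats.ttest_ind(assigned_scores, random_scores)
    if not np.isfinite(t):  # identical constant score vectors
        return SignificanceResult(t_stat=0.0, p_value=1.0)
    return SignificanceResult(t_stat=float(t), p_value=float(p))
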