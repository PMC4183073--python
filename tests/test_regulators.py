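"""Gibbs clustering, tight clusters, sample trees and regulator scores."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import adiponet as an
from adiponet.regulators import (
    SCORE_CAP,
    SampleTree,
    GibbsSampleClusterer,
    TightClusterEnsemble,
    _node_scores,
    build_sample_tree,
    per_run_tree_collections,
    score_genes,
    standardize,
    tight_clusters,
)

from conftest import make_block_expression


def scaled_blocks(block_sizes, within_cor, n_noise=0, seed=0, n_samples=36):
    expr, labels = make_block_expression(block_sizes, within_cor,
                                         n_samples=n_samples, seed=seed,
                                         n_noise=n_noise)
    return standardize(expr), labels


class TestGibbsClustering:
    def test_requires_standardized_input(self):
        expr = pd.DataFrame([[10.0, 20.0, 30.0]], index=["g"], columns=list("abc"))
        with pytest.raises(ValueError, match="centered and scaled"):
            an.gibbs_cluster(expr, seed=0)

    def test_two_separable_blocks_recovered(self):
        expr, labels = scaled_blocks([30, 30], within_cor=0.95, seed=1)
        lab = an.gibbs_cluster(expr, seed=1)
        assert adjusted_rand_score(labels, lab) >= 0.9

    def test_duplicated_gene_stays_in_one_cluster(self):
        rng = np.random.default_rng(2)
        profile = rng.standard_normal(36)
        rows = [profile] * 20 + [rng.standard_normal(36) for _ in range(10)]
        expr = standardize(pd.DataFrame(rows, index=[f"g{i}" for i in range(30)]))
        lab = an.gibbs_cluster(expr, seed=2)
        assert lab.iloc[:20].nunique() == 1

    def test_noise_clusters_carry_no_coexpression(self):
        """On i.i.d. noise the sampler pools exchangeable genes, but any
        cluster it reports has null within-cluster correlation."""
        expr, _ = scaled_blocks([], within_cor=0.5, n_noise=80, seed=3)
        lab = an.gibbs_cluster(expr, seed=3, alpha=0.1)
        for c in lab.unique():
            genes = lab.index[lab == c]
            if len(genes) < 10:
                continue
            cor = np.corrcoef(expr.loc[genes].to_numpy())
            off = cor[np.triu_indices_from(cor, 1)]
            assert abs(off.mean()) < 0.1

    def test_estimator_labels_match_assignments(self):
        expr, _ = scaled_blocks([15, 15], within_cor=0.9, seed=4)
        model = GibbsSampleClusterer(random_state=4).fit(expr)
        assert (model.labels_ == model.assignments_.to_numpy()).all()


class TestTightClusters:
    def test_identical_runs_reproduce_clusters(self):
        run = pd.Series([0] * 12 + [1] * 15, index=[f"g{i}" for i in range(27)])
        cs = tight_clusters([run, run.copy(), run.copy()], min_size=10)
        assert sorted(map(len, cs.clusters.values())) == [12, 15]

    def test_low_frequency_gene_excluded(self):
        genes = [f"g{i}" for i in range(12)]
        stable = pd.Series([0] * 11 + [1], index=genes)
        flaky = pd.Series([0] * 12, index=genes)
        # g11 joins the block in only 4 of 10 runs: below the 0.8 threshold
        runs = [flaky] * 4 + [stable] * 6
        cs = tight_clusters(runs, freq_threshold=0.8, min_size=11)
        assert "g11" not in {g for c in cs.clusters.values() for g in c}

    def test_invariant_to_run_order(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        runs = [pd.Series(rng.integers(0, 3, 40), index=genes) for _ in range(6)]
        a = tight_clusters(runs, min_size=5)
        b = tight_clusters(runs[::-1], min_size=5)
        assert a.clusters == b.clusters
        assert np.allclose(a.coclustering, b.coclustering)

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            tight_clusters([pd.Series([0], index=["g"])])

    def test_ensemble_recovers_planted_blocks(self):
        expr, labels = scaled_blocks([20, 18, 16], within_cor=0.9, n_noise=0, seed=6)
        model = TightClusterEnsemble(n_runs=10, min_cluster_size=10,
                                     random_state=6).fit(expr)
        assert len(model.clusters_) == 3
        assert adjusted_rand_score(labels, model.assignments_) >= 0.8


class TestSampleTree:
    def test_bimodal_profile_splits_at_the_gap(self):
        rng = np.random.default_rng(7)
        z = np.array([0.0] * 18 + [1.0] * 18)
        rows = [3 * z + 0.1 * rng.standard_normal(36) for _ in range(12)]
        expr = pd.DataFrame(rows, index=[f"g{i}" for i in range(12)],
                            columns=[f"s{j:02d}" for j in range(36)])
        tree = build_sample_tree(expr)
        left, right = tree.root_split
        low = frozenset(f"s{j:02d}" for j in range(18))
        assert {frozenset(left), frozenset(right)} == {low, frozenset(expr.columns) - low}

    def test_identical_samples_degenerate(self):
        expr = pd.DataFrame(np.ones((5, 8)), index=[f"g{i}" for i in range(5)],
                            columns=[f"s{j}" for j in range(8)])
        with pytest.warns(UserWarning, match="degenerate"):
            tree = build_sample_tree(expr)
        assert tree.degenerate and not tree.nodes

    def test_nodes_partition_their_parent(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame(rng.standard_normal((10, 20)),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"s{j}" for j in range(20)])
        tree = build_sample_tree(expr)
        root = set(tree.nodes[0][0]) | set(tree.nodes[0][1])
        assert root == set(expr.columns)
        for left, right in tree.nodes:
            assert not set(left) & set(right)


class TestNodeScores:
    @staticmethod
    def node(n_left=18, n_right=18):
        cols = [f"s{j:02d}" for j in range(n_left + n_right)]
        return tuple(cols[:n_left]), tuple(cols[n_left:])

    def test_constant_regulator_scores_zero(self):
        node = self.node()
        x = pd.Series(1.0, index=list(node[0]) + list(node[1]))
        assert an.score_regulator(x, node) == 0.0

    def test_perfect_predictor_reaches_the_cap(self):
        rng = np.random.default_rng(9)
        node = self.node()
        cols = list(node[0]) + list(node[1])
        x = pd.Series(np.r_[np.zeros(18), np.ones(18)] + 0.01 * rng.standard_normal(36),
                      index=cols)
        assert an.score_regulator(x, node) == pytest.approx(0.5 * SCORE_CAP, rel=0.35)

    def test_null_mean_score_is_small(self):
        rng = np.random.default_rng(10)
        node = self.node()
        cols = list(node[0]) + list(node[1])
        scores = [an.score_regulator(pd.Series(rng.standard_normal(36), index=cols), node)
                  for _ in range(200)]
        # nominal gating admits ~5% of nulls at modest -log10 p
        assert np.mean(scores) < 0.3

    def test_matches_statsmodels_likelihood_ratio(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        node = self.node(12, 24)
        cols = list(node[0]) + list(node[1])
        y = np.r_[np.zeros(12), np.ones(24)]
        x = 0.8 * y + rng.standard_normal(36)  # informative but not separable
        z = (x - x.mean()) / x.std()
        fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        p_sm = float(pd.Series(fit.llr_pvalue))
        score = an.score_regulator(pd.Series(x, index=cols), node)
        expected = (12 / 36) * min(-np.log10(p_sm), SCORE_CAP) if p_sm < 0.05 else 0.0
        assert score == pytest.approx(expected, abs=1e-4)


class TestEnsembleScores:
    def make_tree(self):
        cols = [f"s{j:02d}" for j in range(36)]
        return SampleTree(nodes=[(tuple(cols[:18]), tuple(cols[18:]))]), cols

    def test_single_run_single_node_equals_node_score(self):
        tree, cols = self.make_tree()
        rng = np.random.default_rng(12)
        expr = pd.DataFrame([np.r_[np.zeros(18), np.ones(18)] + 0.05 * rng.standard_normal(36)],
                            index=["reg"], columns=cols)
        res = an.ensemble_regulator_scores(expr, ["reg"], [{"C1": tree}])
        node_score = an.score_regulator(expr.loc["reg"], tree.nodes[0])
        assert res.global_score.loc["reg"] == pytest.approx(node_score)

    def test_duplicated_runs_double_the_score(self):
        tree, cols = self.make_tree()
        rng = np.random.default_rng(13)
        expr = pd.DataFrame([np.r_[np.zeros(18), np.ones(18)] + 0.05 * rng.standard_normal(36)],
                            index=["reg"], columns=cols)
        one = an.ensemble_regulator_scores(expr, ["reg"], [{"C1": tree}])
        two = an.ensemble_regulator_scores(expr, ["reg"], [{"C1": tree}] * 2)
        assert two.global_score.loc["reg"] == pytest.approx(2 * one.global_score.loc["reg"])

    def test_absent_regulator_skipped_with_warning(self):
        tree, cols = self.make_tree()
        expr = pd.DataFrame(np.random.default_rng(14).standard_normal((2, 36)),
                            index=["a", "b"], columns=cols)
        with pytest.warns(UserWarning, match="absent"):
            res = an.ensemble_regulator_scores(expr, ["a", "ghost"], [{"C1": tree}])
        assert list(res.global_score.index) == ["a"]


class TestTopRegulators:
    def test_percent_ceiling(self):
        scores = pd.Series(np.arange(100, dtype=float),
                           index=[f"r{i:03d}" for i in range(100)])
        assert an.top_regulators(scores, 0.01) == ["r099"]
        assert len(an.top_regulators(scores, 1.0)) == 100

    def test_candidate_count_from_the_study_scale(self):
        scores = pd.Series(np.arange(1104, dtype=float),
                           index=[f"r{i:04d}" for i in range(1104)])
        assert len(an.top_regulators(scores, 0.01)) == 12  # ceil(11.04)

    def test_ties_break_by_identifier(self):
        scores = pd.Series([1.0, 1.0, 0.0], index=["b", "a", "c"])
        assert an.top_regulators(scores, 0.3) == ["a"]


class TestSignificance:
    def test_identical_scores_give_p_one(self):
        cols = [f"s{j}" for j in range(10)]
        expr = pd.DataFrame(np.ones((30, 10)) * np.arange(10),
                            index=[f"g{i}" for i in range(30)], columns=cols)
        scores = pd.Series(1.0, index=expr.index)
        res = an.regulator_significance(expr, [], ["g0", "g1"], ["g0", "g1"],
                                        n_random=5, seed=0, scores=scores)
        assert res.p_value == 1.0 and res.t_stat == 0.0

    def test_planted_regulators_significantly_outscore_random(self):
        study = an.simulate_study(an.SimulationConfig(
            n_genes=300, module_sizes=(40, 35, 30), module_trait_cor=(0.7, 0.6, 0.5),
            n_regulators=2, n_candidate_regulators=100, n_diff_hubs=0,
            n_lean_hubs=0, n_global_factors=0, seed=4,
        ))
        counts = an.filter_low_expression(study.counts)
        expr = an.normalize(counts, an.size_factors(counts), study.phenotypes)
        scaled = standardize(an.variance_filter(expr, 0.5))
        ens = TightClusterEnsemble(n_runs=5, random_state=4).fit(scaled)
        colls = per_run_tree_collections(scaled, ens.runs_, min_size=10)
        planted = list(study.truth.regulator_of_cluster)
        module_genes = {g for g, m in study.truth.module_of_gene.items()
                        if m != "background"}
        universe = [g for g in expr.index
                    if g in set(study.candidate_regulators) or g not in module_genes]
        res = an.regulator_significance(
            standardize(expr.loc[universe]), colls, planted,
            study.candidate_regulators, n_random=40, seed=5,
        )
        assert res.p_value < 0.01
        assert res.t_stat > 0

    def test_insufficient_pool_rejected(self):
        cols = [f"s{j}" for j in range(10)]
        expr = pd.DataFrame(np.random.default_rng(15).standard_normal((3, 10)),
                            index=["a", "b", "c"], columns=cols)
        with pytest.raises(ValueError, match="not enough"):
            an.regulator_significance(expr, [], ["a", "b"], ["a", "b", "c"],
                                      n_random=5, seed=0)
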