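"""Adjacency, TOM, scale-free fit and module detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import adiponet as an
from adiponet.network import WGCNA, _fallback_beta, scale_free_fit

from conftest import make_block_expression


def frame(mat, prefix="g"):
    ids = [f"{prefix}{i + 1}" for i in range(len(mat))]
    return pd.DataFrame(mat, index=ids, columns=ids)


def random_adjacency(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return frame(a)


def tom_oracle(a):
    """Explicit double-loop topological overlap."""
    n = len(a)
    k = [sum(a[i][j] for j in range(n) if j != i) for i in range(n)]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i][u] * a[u][j] for u in range(n) if u not in (i, j))
            t[i][j] = (l + a[i][j]) / (min(k[i], k[j]) + 1 - a[i][j])
    return t


class TestCorrelation:
    def test_hand_computed_pair(self):
        expr = pd.DataFrame([[1, 2, 3], [1, 2, 4]], index=["x", "y"],
                            columns=["a", "b", "c"], dtype=float)
        cor = an.correlation_matrix(expr)
        assert cor.loc["x", "y"] == pytest.approx(0.98198, abs=1e-5)
        assert cor.loc["x", "x"] == 1.0

    def test_anticorrelated_profiles(self):
        x = np.array([1.0, 3.0, 2.0, 5.0])
        expr = pd.DataFrame([x, -x], index=["x", "y"], columns=list("abcd"))
        assert an.correlation_matrix(expr).loc["x", "y"] == pytest.approx(-1.0)

    def test_zero_variance_gene_named_in_error(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]],
                            index=["flat", "ok"], columns=list("abc"))
        with pytest.raises(ValueError, match="flat"):
            an.correlation_matrix(expr)


class TestAdjacency:
    @pytest.mark.parametrize("r, beta, expected",
                             [(-0.8, 2, 0.64), (0.5, 7, 0.0078125), (0.0, 3, 0.0)])
    def test_powers(self, r, beta, expected):
        cor = frame([[1.0, r], [r, 1.0]])
        assert an.adjacency(cor, beta).iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_identity_maps_to_identity(self):
        cor = frame(np.eye(4))
        assert np.allclose(an.adjacency(cor, 7), np.eye(4))

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            an.adjacency(frame(np.eye(2)), 0)

    def test_monotone_in_absolute_correlation(self):
        rng = np.random.default_rng(0)
        r = np.sort(rng.uniform(-1, 1, 50))
        for beta in (1, 3, 7):
            a = np.abs(r) ** beta
            order = np.argsort(np.abs(r))
            assert (np.diff(a[order]) >= -1e-15).all()


class TestConnectivity:
    def test_identity_gives_zero(self):
        assert (an.connectivity(frame(np.eye(3))) == 0).all()

    def test_uniform_off_diagonal(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        assert np.allclose(an.connectivity(frame(a)), 1.0)

    def test_matches_double_loop_oracle(self):
        adj = random_adjacency(6, seed=1)
        a = adj.to_numpy()
        expected = [sum(a[i][j] for j in range(6) if j != i) for i in range(6)]
        assert np.abs(an.connectivity(adj).to_numpy() - expected).max() <= 1e-12


class TestScaleFreeFit:
    def test_exact_log_log_line_gives_unit_r_squared(self):
        # value j appears 2520/j times: freq strictly proportional to 1/j
        k = np.concatenate([np.full(2520 // j, float(j)) for j in range(1, 11)])
        fit = scale_free_fit(k, n_bins=10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-1.0, abs=1e-9)

    def test_uniform_connectivity_smoke(self):
        rng = np.random.default_rng(0)
        fit = scale_free_fit(rng.uniform(1, 100, 2000))
        assert fit.r_squared < 1.0

    def test_degenerate_all_equal_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit(np.full(100, 3.0))


class TestPickBeta:
    def test_selection_rule_consistent_with_sweep(self, default_expression):
        beta, sweep = an.pick_beta(default_expression)
        neg = sweep[sweep.slope < 0]
        crossing = neg[neg.r_squared >= 0.90]
        if not crossing.empty:
            assert beta == int(crossing.beta.iloc[0])
        else:
            assert beta == _fallback_beta(default_expression.shape[1]) == 7

    def test_empty_candidates_rejected(self, default_expression):
        with pytest.raises(ValueError):
            an.pick_beta(default_expression, candidate_betas=[])


class TestTOM:
    def test_zero_off_diagonal_gives_zero_overlap(self):
        t = an.tom(frame(np.eye(5)))
        off = t.to_numpy()[~np.eye(5, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_perfect_clique_gives_unit_overlap(self):
        t = an.tom(frame(np.ones((3, 3))))
        assert np.allclose(t, 1.0)

    def test_matches_double_loop_oracle(self):
        adj = random_adjacency(15, seed=2)
        expected = tom_oracle(adj.to_numpy())
        assert np.abs(an.tom(adj).to_numpy() - expected).max() <= 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_bounded_in_unit_interval(self, seed):
        t = an.tom(random_adjacency(12, seed=seed)).to_numpy()
        assert t.min() >= 0.0 and t.max() <= 1.0


class TestDetectModules:
    def test_two_perfect_blocks_recovered_exactly(self):
        expr, labels = make_block_expression([60, 60], within_cor=0.98, seed=4)
        net = WGCNA(beta=6, min_module_size=50).fit(expr)
        assert adjusted_rand_score(labels, net.modules_) == pytest.approx(1.0)
        assert set(net.modules_.unique()) == {"turquoise", "blue"}

    def test_noise_with_min_size_all_genes_stays_grey(self):
        expr, _ = make_block_expression([], within_cor=0.5, n_noise=60, seed=5)
        t = an.tom(an.adjacency(an.correlation_matrix(expr), 6))
        labels = an.detect_modules(t, min_size=60)
        assert (labels == "grey").all()

    def test_fewer_genes_than_min_size_warns_grey(self):
        expr, _ = make_block_expression([10], within_cor=0.9, seed=6)
        t = an.tom(an.adjacency(an.correlation_matrix(expr), 6))
        with pytest.warns(UserWarning):
            labels = an.detect_modules(t, min_size=50)
        assert (labels == "grey").all()

    def test_static_quantile_cut_still_available(self):
        expr, labels = make_block_expression([60, 60], within_cor=0.98, seed=7)
        t = an.tom(an.adjacency(an.correlation_matrix(expr), 6))
        out = an.detect_modules(t, min_size=50, cut_height_quantile=0.99)
        assert adjusted_rand_score(labels, out) == pytest.approx(1.0)

    def test_permutation_equivariance(self):
        expr, _ = make_block_expression([55, 50], within_cor=0.9, n_noise=20, seed=8)
        t = an.tom(an.adjacency(an.correlation_matrix(expr), 6))
        base = an.detect_modules(t, min_size=50)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(expr))
        tp = t.iloc[perm, perm]
        permuted = an.detect_modules(tp, min_size=50)
        assert (permuted.loc[base.index] == base).all()


class TestWGCNAEstimator:
    def test_fit_exposes_fitted_attributes(self):
        expr, _ = make_block_expression([60], within_cor=0.9, n_noise=10, seed=9)
        net = WGCNA(beta=6, min_module_size=50).fit(expr)
        assert net.beta_ == 6
        assert net.tom_.shape == (70, 70)
        assert len(net.labels_) == 70
        assert net.scale_free_sweep_ is None

    def test_sklearn_param_interface(self):
        net = WGCNA(beta=9, min_module_size=30)
        assert WGCNA(**net.get_params()).get_params() == net.get_params()
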