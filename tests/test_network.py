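"""Signed co-expression networks: robust correlation, adjacency, scale-free
fit, topological overlap, module detection, intramodular connectivity."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import adjusted_rand_score

from plastevo.network import (_scale_free_r2, bicor_matrix, connectivity,
                              detect_modules, intramodular_connectivity,
                              mad_filter, pick_beta, scale_free_fit,
                              signed_adjacency, tom_similarity)


class TestMadFilter:
    def test_constant_and_near_constant_removed(self):
        expr = pd.DataFrame({
            "s1": [1.0, 5.0, 1.0], "s2": [1.0, 5.0, 2.0], "s3": [1.0, 5.0, 3.0],
            "s4": [1.0, 5.0, 4.0], "s5": [1.0, 9.0, 5.0],
        }, index=["const", "one_off", "monotone"])
        kept = mad_filter(expr)
        # a gene constant in all but one sample still has zero median deviation
        assert list(kept) == ["monotone"]

    def test_all_removed_raises(self):
        expr = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError):
            mad_filter(expr)


class TestBicor:
    def test_perfect_relations(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        expr = pd.DataFrame([x, x, -x], index=["a", "b", "c"])
        cor = bicor_matrix(expr)
        assert cor.loc["a", "b"] == pytest.approx(1.0)
        assert cor.loc["a", "c"] == pytest.approx(-1.0)

    def test_outlier_robustness_vs_pearson(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + 0.2 * rng.normal(size=30)
        y_spiked = y.copy()
        y_spiked[0] = 40.0
        clean = pearsonr(x, y).statistic
        contaminated = pearsonr(x, y_spiked).statistic
        robust = bicor_matrix(pd.DataFrame([x, y_spiked])).iloc[0, 1]
        assert abs(robust - clean) < abs(contaminated - clean)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            bicor_matrix(pd.DataFrame(np.ones((3, 4))))

    def test_zero_mad_gene_falls_back_to_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=11)
        flat = np.zeros(11)
        flat[0] = 1.0  # median deviation zero, but not constant
        expr = pd.DataFrame([x, flat])
        with pytest.warns(UserWarning, match="Pearson"):
            cor = bicor_matrix(expr)
        assert np.isfinite(cor.iloc[0, 1])


class TestSignedAdjacency:
    @pytest.mark.parametrize("cor, beta, expected", [
        (1.0, 12, 1.0),
        (-1.0, 12, 0.0),
        (0.0, 12, 2.0**-12),
    ])
    def test_closed_form(self, cor, beta, expected):
        mat = np.array([[1.0, cor], [cor, 1.0]])
        adj = signed_adjacency(mat, beta)
        assert adj[0, 1] == pytest.approx(expected)
        assert adj[0, 0] == 1.0

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError):
            signed_adjacency(np.eye(2), 0.5)

    def test_raising_beta_strictly_shrinks_partial_edges(self):
        rng = np.random.default_rng(3)
        cor = np.clip(rng.uniform(-0.99, 0.99, (30, 30)), -0.99, 0.99)
        cor = (cor + cor.T) / 2
        np.fill_diagonal(cor, 1.0)
        a6, a12 = signed_adjacency(cor, 6), signed_adjacency(cor, 12)
        off = ~np.eye(30, dtype=bool)
        positive = (cor > -1) & off
        assert (a12[positive] < a6[positive]).all()


class TestScaleFreeFit:
    def test_power_law_connectivity_fits_tightly(self):
        u = (np.arange(5000) + 0.5) / 5000
        k = 10.0 * (1 - u) ** (-1 / 2.0)  # Pareto-tail connectivity
        assert _scale_free_r2(k) > 0.95

    def test_uniform_adjacency_warns_and_reports_zero(self):
        adj = np.full((60, 60), 0.5)
        np.fill_diagonal(adj, 1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            r2, mean_k = scale_free_fit(adj)
        assert r2 == 0.0
        assert mean_k == pytest.approx(59 * 0.5)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.eye(10))


@pytest.fixture(scope="module")
def modular_expression():
    """Four 50-gene modules plus 100 background genes over 60 samples."""
    rng = np.random.default_rng(3)
    n_s = 60
    blocks = []
    for m in range(4):
        factor = rng.standard_normal(n_s)
        loading = rng.uniform(0.3, 1.2, 50)
        blocks.append(loading[:, None] * factor + 0.4 * rng.standard_normal((50, n_s)))
    blocks.append(rng.standard_normal((100, n_s)))
    return pd.DataFrame(np.vstack(blocks))


class TestPickBeta:
    def test_module_fixture_picks_first_qualifying_power(self, modular_expression):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, diag = pick_beta(modular_expression, grid=range(2, 15, 2),
                                   min_mean_k=3)
        qualifying = diag[(diag["scale_free_r2"] > 0.8)
                          & (diag["mean_connectivity"] >= 3)]
        assert beta == int(qualifying["beta"].iloc[0]) == 12

    def test_singleton_grid_returned_unconditionally(self, modular_expression):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta, _ = pick_beta(modular_expression, grid=[12], min_mean_k=3)
        assert beta == 12

    def test_pure_noise_falls_back_with_warning(self):
        rng = np.random.default_rng(9)
        noise = pd.DataFrame(rng.standard_normal((120, 40)))
        with pytest.warns(UserWarning, match="argmax"):
            beta, diag = pick_beta(noise, grid=(2, 6, 12))
        assert beta in set(diag["beta"])


class TestTomSimilarity:
    def test_three_gene_closed_form(self):
        adj = np.full((3, 3), 0.5)
        np.fill_diagonal(adj, 1.0)
        tom = tom_similarity(adj)
        # (a^2 + a) / (a + 1 - a) with k_i = 2a = 1: 0.75 / 1.5 = 0.5
        assert tom[0, 1] == pytest.approx(0.5)
        assert np.allclose(np.diag(tom), 1.0)

    def test_identical_fully_connected_pair(self):
        adj = np.ones((4, 4))
        assert tom_similarity(adj)[0, 1] == pytest.approx(1.0)

    def test_isolated_gene_has_no_overlap(self):
        adj = np.full((5, 5), 0.6)
        np.fill_diagonal(adj, 1.0)
        adj[4, :] = adj[:, 4] = 1e-9
        adj[4, 4] = 1.0
        tom = tom_similarity(adj)
        assert (tom[4, :4] < 1e-6).all()

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 1, (12, 12))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        n = a.shape[0]
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                k_i = sum(a[i, u] for u in range(n) if u != i)
                k_j = sum(a[j, u] for u in range(n) if u != j)
                expected = (shared + a[i, j]) / (min(k_i, k_j) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0, 1, (40, 40))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(a)
        assert ((tom >= 0) & (tom <= 1)).all()
        assert np.allclose(tom, tom.T)


class TestDetectModules:
    def test_planted_blocks_recovered_exactly(self, planted_partition):
        expr, truth, _ = planted_partition
        adj = signed_adjacency(bicor_matrix(expr).values, 12)
        labels = detect_modules(1 - tom_similarity(adj), min_size=30, deep_split=2)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_small_block_never_its_own_module(self):
        rng = np.random.default_rng(11)
        n_s = 60
        factor = rng.standard_normal(n_s)
        block = rng.uniform(0.8, 1.2, 10)[:, None] * factor \
            + 0.3 * rng.standard_normal((10, n_s))
        noise = rng.standard_normal((60, n_s))
        expr = pd.DataFrame(np.vstack([block, noise]))
        adj = signed_adjacency(bicor_matrix(expr).values, 6)
        labels = detect_modules(1 - tom_similarity(adj), min_size=30, deep_split=2)
        for m in set(labels) - {0}:
            members = set(np.flatnonzero(labels == m))
            assert not members <= set(range(10))

    def test_min_size_above_n_leaves_all_unassigned(self, planted_partition):
        expr, _, _ = planted_partition
        adj = signed_adjacency(bicor_matrix(expr).values, 12)
        labels = detect_modules(1 - tom_similarity(adj), min_size=101)
        assert set(labels) == {0}

    def test_background_genes_left_unassigned(self, modular_expression):
        adj = signed_adjacency(bicor_matrix(modular_expression).values, 12)
        labels = detect_modules(1 - tom_similarity(adj), min_size=30, deep_split=2)
        truth = np.repeat([1, 2, 3, 4, 0], [50, 50, 50, 50, 100])
        in_module = truth > 0
        assert adjusted_rand_score(truth[in_module], labels[in_module]) > 0.95
        assert (labels[~in_module] > 0).mean() < 0.1


class TestIntramodularConnectivity:
    def test_three_gene_module_closed_form(self):
        adj = np.full((3, 3), 0.5)
        np.fill_diagonal(adj, 1.0)
        conn = intramodular_connectivity(adj, np.array([1, 1, 1]))
        assert np.allclose(conn["k_im"], 1.0)
        assert np.allclose(conn["k_im_scaled"], 1.0)

    def test_two_gene_module(self):
        adj = np.array([[1.0, 0.3], [0.3, 1.0]])
        conn = intramodular_connectivity(adj, np.array([1, 1]))
        assert np.allclose(conn["k_im"], 0.3)

    def test_hub_attains_scaled_one_exactly(self):
        adj = np.array([
            [1.0, 0.9, 0.8, 0.1],
            [0.9, 1.0, 0.5, 0.1],
            [0.8, 0.5, 1.0, 0.1],
            [0.1, 0.1, 0.1, 1.0],
        ])
        conn = intramodular_connectivity(adj, np.array([1, 1, 1, 0]))
        assert conn["k_im_scaled"].iloc[0] == 1.0
        assert (conn["k_im_scaled"].iloc[1:3] < 1.0).all()
        assert np.isnan(conn.loc[3, "k_im"])  # unassigned gene

    def test_hubs_track_planted_loadings(self, planted_partition):
        expr, truth, loading = planted_partition
        adj = signed_adjacency(bicor_matrix(expr).values, 12)
        labels = detect_modules(1 - tom_similarity(adj), min_size=30, deep_split=2)
        conn = intramodular_connectivity(adj, labels)
        assigned = labels > 0
        rho = spearmanr(conn["k_im"].values[assigned], loading[assigned]).statistic
        assert rho > 0.8


def test_whole_network_connectivity_definition():
    adj = np.array([[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]])
    assert np.allclose(connectivity(adj), [0.6, 0.8, 1.0])
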