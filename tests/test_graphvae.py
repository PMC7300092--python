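import numpy as np
import pytest

from scdiffvae import graphvae as gv


class TestCorrelationGraph:
    def test_identical_cells_single_mutual_edge(self):
        x = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        g = gv.correlation_graph(x)
        np.testing.assert_array_equal(g.edge_list(), [[0, 1]])

    def test_hand_correlations(self):
        # corr(c1, c2) = 1, corr(., c3) = -1: only (0, 1); c3 isolated
        x = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]])
        with pytest.warns(UserWarning, match="isolated"):
            g = gv.correlation_graph(x)
        np.testing.assert_array_equal(g.edge_list(), [[0, 1]])
        assert g.A[2].sum() == 0

    def test_matches_bruteforce_argmax_oracle(self, rng):
        x = rng.standard_normal((10, 8))
        g = gv.correlation_graph(x)
        expected = np.zeros((10, 10), dtype=int)
        for i in range(10):
            best, best_c = None, 0.0
            for j in range(10):
                if j == i:
                    continue
                c = np.corrcoef(x[i], x[j])[0, 1]
                if c > best_c:
                    best, best_c = j, c
            if best is not None:
                expected[i, best] = 1
        expected = np.maximum(expected, expected.T)
        np.testing.assert_array_equal(g.A, expected)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal((8, 12))
        a = rng.uniform(0.5, 3.0, size=(8, 1))
        b = rng.standard_normal((8, 1))
        g1 = gv.correlation_graph(x)
        g2 = gv.correlation_graph(a * x + b)
        np.testing.assert_array_equal(g1.A, g2.A)

    def test_zero_variance_cell_isolated(self, rng):
        x = rng.standard_normal((5, 6))
        x[2] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            g = gv.correlation_graph(x)
        assert g.A[2].sum() == 0


class TestNormalizeAdjacency:
    def test_identity_graph(self):
        g = gv.CellGraph(A=np.zeros((3, 3), dtype=int))
        np.testing.assert_allclose(gv.normalize_adjacency(g), np.eye(3))

    def test_two_node_complete(self):
        g = gv.CellGraph(A=np.array([[0, 1], [1, 0]]))
        np.testing.assert_allclose(gv.normalize_adjacency(g), np.full((2, 2), 0.5))

    def test_three_node_path_hand_values(self):
        g = gv.CellGraph(A=np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]))
        a_norm = gv.normalize_adjacency(g)
        assert a_norm[0, 0] == pytest.approx(0.5)
        assert a_norm[0, 1] == pytest.approx(1 / np.sqrt(6))
        assert a_norm[1, 1] == pytest.approx(1 / 3)
        assert a_norm[0, 2] == pytest.approx(0.0)
        np.testing.assert_allclose(a_norm, a_norm.T)

    def test_eigenvalues_bounded(self, rng):
        for _ in range(5):
            a = (rng.uniform(size=(7, 7)) > 0.6).astype(int)
            a = np.maximum(a, a.T)
            np.fill_diagonal(a, 0)
            eig = np.linalg.eigvalsh(gv.normalize_adjacency(gv.CellGraph(A=a)))
            assert eig.min() >= -1 - 1e-10 and eig.max() <= 1 + 1e-10


class TestGCNLayer:
    def test_identity_propagation(self, rng):
        x = rng.standard_normal((4, 3))
        np.testing.assert_array_equal(gv.gcn_layer(np.eye(4), x, np.eye(3), "linear"), x)

    def test_single_node_arithmetic(self):
        out = gv.gcn_layer(np.array([[1.0]]), np.array([[2.0]]), np.array([[3.0]]), "relu")
        assert out[0, 0] == 6.0

    def test_matches_message_passing_oracle(self, rng):
        a_norm = rng.uniform(size=(5, 5))
        a_norm = (a_norm + a_norm.T) / 2
        x = rng.standard_normal((5, 3))
        w = rng.standard_normal((3, 2))
        out = gv.gcn_layer(a_norm, x, w, "linear")
        expected = np.zeros((5, 2))
        for i in range(5):
            for f in range(2):
                for j in range(5):
                    for d in range(3):
                        expected[i, f] += a_norm[i, j] * x[j, d] * w[d, f]
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_identity_adjacency_reduces_to_dense(self, rng):
        x = rng.standard_normal((6, 4))
        w = rng.standard_normal((4, 3))
        np.testing.assert_allclose(gv.gcn_layer(np.eye(6), x, w, "linear"), x @ w, atol=1e-12)


def zero_graph_model(n_features, cfg):
    model = gv.GraphDiffVAEModel(n_features, cfg)
    for p in model.params():
        p.value[...] = 0.0
    return model


class TestEncodeDecode:
    @pytest.fixture
    def graph4(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1
        return gv.CellGraph(A=a)

    def test_zero_weights_zero_posterior(self, graph4, rng):
        cfg = gv.GraphDiffVAEConfig(hidden_features=6, latent_features=3)
        model = zero_graph_model(5, cfg)
        mu, log_var = gv.graph_encode(graph4, rng.standard_normal((4, 5)), model)
        np.testing.assert_array_equal(mu, 0.0)
        np.testing.assert_array_equal(log_var, 0.0)

    def test_output_shapes(self, graph4, rng):
        cfg = gv.GraphDiffVAEConfig(hidden_features=8, latent_features=50)
        model = gv.GraphDiffVAEModel(5, cfg)
        mu, log_var = gv.graph_encode(graph4, rng.standard_normal((4, 5)), model)
        assert mu.shape == (4, 50) and log_var.shape == (4, 50)

    def test_isolated_node_locality(self, rng):
        """An isolated node's posterior depends only on its own features."""
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = 1  # node 3 isolated
        graph = gv.CellGraph(A=a)
        cfg = gv.GraphDiffVAEConfig(hidden_features=6, latent_features=3, seed=2)
        model = gv.GraphDiffVAEModel(5, cfg)
        x = rng.standard_normal((4, 5))
        mu_a, _ = gv.graph_encode(graph, x, model)
        x2 = x.copy()
        x2[:3] += rng.standard_normal((3, 5))  # perturb everyone else
        mu_b, _ = gv.graph_encode(graph, x2, model)
        np.testing.assert_allclose(mu_a[3], mu_b[3], atol=1e-12)
        assert not np.allclose(mu_a[:3], mu_b[:3])

    def test_zero_decoder_gives_half(self, graph4, rng):
        cfg = gv.GraphDiffVAEConfig(hidden_features=6, latent_features=3)
        model = zero_graph_model(5, cfg)
        pred = gv.graph_decode(graph4, rng.standard_normal((4, 5)), np.zeros((4, 3)), model)
        np.testing.assert_allclose(pred.A_hat, 0.5)

    def test_a_hat_symmetric(self, graph4, rng):
        cfg = gv.GraphDiffVAEConfig(hidden_features=6, latent_features=3, seed=1)
        model = gv.GraphDiffVAEModel(5, cfg)
        pred = gv.graph_decode(graph4, rng.standard_normal((4, 5)), rng.standard_normal((4, 3)), model)
        np.testing.assert_array_equal(pred.A_hat, pred.A_hat.T)
        np.testing.assert_allclose(pred.Z_star, 0.5 * (pred.Z + pred.Z_prime))


class TestLoss:
    def test_perfect_reconstruction_standard_posterior(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        loss = gv.graphvae_loss(a, np.full((2, 2), 1 - 1e-9), np.zeros((2, 1)), np.zeros((2, 1)))
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_kl_hand_value(self):
        # one node, M = 1, mu = 1, sigma = 1 -> KL = 0.5; make BCE exact zero-ish
        a = np.array([[1.0]])
        loss = gv.graphvae_loss(a, np.array([[1 - 1e-9]]), np.array([[1.0]]), np.array([[0.0]]))
        assert loss == pytest.approx(0.5, abs=1e-5)

    def test_nll_matches_elementwise_oracle(self, rng):
        a = (rng.uniform(size=(5, 5)) > 0.5).astype(float)
        a_hat = rng.uniform(0.05, 0.95, size=(5, 5))
        w = 2.5
        loss = gv.graphvae_loss(a, a_hat, np.zeros((5, 2)), np.zeros((5, 2)), edge_pos_weight=w)
        expected = 0.0
        for i in range(5):
            for j in range(5):
                expected -= w * a[i, j] * np.log(a_hat[i, j]) + (1 - a[i, j]) * np.log(1 - a_hat[i, j])
        assert loss == pytest.approx(expected / 5, abs=1e-10)


@pytest.fixture(scope="module")
def small_graph_data():
    from scdiffvae import preprocess, synthetic

    ds = synthetic.generate_expression(synthetic.SyntheticSpec(
        n_cells=40, n_genes=20, n_clusters=2, markers_per_cluster=4, seed=6))
    unit = preprocess.minmax_scale(ds.expression)
    graph = synthetic.generate_labeled_graph(ds, k=2, seed=6)
    return unit, graph


class TestTraining:
    def test_zero_epochs_contract(self, small_graph_data):
        unit, graph = small_graph_data
        cfg = gv.GraphDiffVAEConfig(hidden_features=8, latent_features=4, epochs=0, seed=0)
        pred, _, history = gv.train_graph_diffvae(unit, graph, cfg)
        assert history == []
        assert pred.A_hat.shape == (40, 40)
        np.testing.assert_array_equal(pred.A_hat, pred.A_hat.T)
        assert (pred.A_hat > 0).all() and (pred.A_hat < 1).all()

    def test_loss_decreases_and_deterministic(self, small_graph_data):
        unit, graph = small_graph_data
        cfg = gv.GraphDiffVAEConfig(hidden_features=16, latent_features=4, epochs=30,
                                    learning_rate=0.01, seed=3)
        pred_a, _, hist_a = gv.train_graph_diffvae(unit, graph, cfg)
        assert hist_a[-1] < hist_a[0]
        pred_b, _, hist_b = gv.train_graph_diffvae(unit, graph, cfg)
        assert hist_a == hist_b
        np.testing.assert_array_equal(pred_a.A_hat, pred_b.A_hat)

    def test_shape_mismatch_rejected(self, small_graph_data):
        unit, graph = small_graph_data
        cfg = gv.GraphDiffVAEConfig(hidden_features=8, latent_features=4, epochs=1)
        with pytest.raises(ValueError, match="disagree"):
            gv.train_graph_diffvae(unit.values[:10], graph, cfg)


class TestPredictLinks:
    def test_uniform_half_with_high_threshold(self):
        a_hat = np.full((5, 5), 0.5)
        novel, known = gv.predict_links(a_hat, threshold=0.6)
        assert len(novel) == 0

    def test_threshold_zero_returns_all_pairs(self):
        a_hat = np.full((6, 6), 0.5)
        novel, _ = gv.predict_links(a_hat, threshold=0.0)
        assert len(novel) == 6 * 5 // 2

    def test_top_q_matches_sorting_oracle(self, rng):
        a_hat = rng.uniform(size=(4, 4))
        a_hat = (a_hat + a_hat.T) / 2
        novel, _ = gv.predict_links(a_hat, top_q=3)
        iu, ju = np.triu_indices(4, 1)
        scores = sorted(a_hat[iu, ju], reverse=True)[:3]
        np.testing.assert_allclose(sorted(novel[:, 2], reverse=True), scores, atol=1e-12)

    def test_input_edges_reported_separately(self):
        a_hat = np.full((3, 3), 0.9)
        graph = gv.CellGraph(A=np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        novel, known = gv.predict_links(a_hat, input_graph=graph, threshold=0.5)
        assert len(known) == 1 and len(novel) == 2
        assert (known[0][:2] == [0, 1]).all()


class TestGraphIO:
    def test_edge_list_roundtrip(self, tmp_path, rng):
        a = (rng.uniform(size=(6, 6)) > 0.5).astype(int)
        a = np.maximum(a, a.T)
        np.fill_diagonal(a, 0)
        g = gv.CellGraph(A=a)
        gv.write_graph(g, tmp_path / "e.tsv")
        back = gv.read_graph(tmp_path / "e.tsv", g.cell_ids)
        np.testing.assert_array_equal(back.A, g.A)
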