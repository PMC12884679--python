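import numpy as np
import pytest
import scipy.sparse as sp

from retinograph.gcn import (
    GCNConfig,
    ce_loss,
    combined_loss,
    dice_loss,
    forward,
    gcn_layer,
    init_params,
    labels_to_image,
    train_gcn,
)
from retinograph.graph import build_graph, extract_node_features, normalize_adjacency
from retinograph.labels import ARTERY, BACKGROUND, UNDEFINED, VEIN
from retinograph.nn import Tensor


def _graph_from_mask(mask, feats):
    g = build_graph(np.asarray(mask, dtype=bool))
    return extract_node_features(g, np.asarray(feats, dtype=np.float32))


class TestGcnLayer:
    def test_isolated_nodes_identity(self):
        # two isolated self-looped nodes, identity weights, non-negative H
        mask = np.zeros((1, 3), dtype=bool)
        mask[0, 0] = mask[0, 2] = True
        g = _graph_from_mask(mask, np.arange(3, dtype=float).reshape(1, 1, 3) + 1)
        w_hat = normalize_adjacency(g)
        out = gcn_layer(g.features, w_hat, np.eye(1))
        np.testing.assert_allclose(out.data, g.features, atol=1e-6)

    def test_k2_hand_example(self):
        # K2 with self-loops: W_hat entries all 0.5; H=[[2],[0]], weight 1
        mask = np.ones((1, 2), dtype=bool)
        g = build_graph(mask)
        g.features = np.array([[2.0], [0.0]], dtype=np.float32)
        out = gcn_layer(g.features, normalize_adjacency(g), np.array([[1.0]]))
        np.testing.assert_allclose(out.data, [[1.0], [1.0]], atol=1e-6)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        mask = rng.random((6, 6)) > 0.5
        g = _graph_from_mask(mask, rng.random((2, 6, 6)))
        w_hat = normalize_adjacency(g)
        w = rng.standard_normal((2, 3))
        out = gcn_layer(g.features, w_hat, w).data
        perm = rng.permutation(g.n_nodes)
        p = sp.csr_matrix(np.eye(g.n_nodes)[perm])
        out_p = gcn_layer(g.features[perm], p @ w_hat @ p.T, w).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-5)

    def test_dim_mismatch(self):
        mask = np.ones((1, 2), dtype=bool)
        g = _graph_from_mask(mask, np.zeros((2, 1, 2)))
        with pytest.raises(ValueError, match="feature dim"):
            gcn_layer(g.features, normalize_adjacency(g), np.eye(3))


class TestForward:
    def _setup(self, seed=0, n_layers=2):
        rng = np.random.default_rng(seed)
        mask = rng.random((8, 8)) > 0.4
        g = _graph_from_mask(mask, rng.random((3, 8, 8)))
        cfg = GCNConfig(n_layers=n_layers, hidden_dim=5, seed=seed)
        return g, cfg, init_params(cfg, 3)

    def test_rows_sum_to_one(self):
        g, cfg, params = self._setup()
        pred = forward(g, cfg, params)
        np.testing.assert_allclose(pred.scores.sum(axis=1), 1.0, atol=1e-6)
        assert pred.scores.min() >= 0

    def test_single_layer_equals_layer_plus_softmax(self):
        g, cfg, params = self._setup(n_layers=1)
        pred = forward(g, cfg, params)
        from retinograph import nn

        manual = nn.softmax_rows(
            gcn_layer(g.features, normalize_adjacency(g), params.weights[0]))
        np.testing.assert_allclose(pred.scores, manual.data, atol=1e-6)

    def test_missing_features(self):
        g = build_graph(np.ones((2, 2), dtype=bool))
        cfg = GCNConfig()
        with pytest.raises(ValueError, match="features"):
            forward(g, cfg, init_params(cfg, 1))

    def test_identical_inputs_identical_outputs(self):
        # two connected nodes with identical features get identical scores
        mask = np.ones((1, 2), dtype=bool)
        g = _graph_from_mask(mask, np.full((2, 1, 2), 0.7))
        cfg = GCNConfig(seed=1)
        pred = forward(g, cfg, init_params(cfg, 2))
        np.testing.assert_allclose(pred.scores[0], pred.scores[1], atol=1e-7)


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        g = np.array([1.0, 0.0, 1.0])
        assert float(dice_loss(g, g).data) == pytest.approx(0.0, abs=1e-5)

    def test_disjoint_near_one(self):
        out = dice_loss(np.ones(4), np.zeros(4))
        assert float(out.data) == pytest.approx(1.0, abs=1e-5)

    def test_worked_example_third(self):
        out = dice_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5]), eps=1e-12)
        assert float(out.data) == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_printed_eps_placement(self):
        g = np.array([1.0, 0.0])
        h = np.array([0.5, 0.5])
        sym = float(dice_loss(g, h, eps=0.5, eps_placement="symmetric").data)
        pri = float(dice_loss(g, h, eps=0.5, eps_placement="printed").data)
        assert sym == pytest.approx(1 - 1.5 / 2.0)
        assert pri == pytest.approx(1 - 1.5 / 1.5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros(2), np.zeros(3))


class TestCeLoss:
    def test_perfect_binary(self):
        b = np.array([1.0, 0.0])
        assert float(ce_loss(b, b).data) == pytest.approx(0.0, abs=1e-5)

    def test_half_ln2(self):
        assert float(ce_loss(np.array([1.0]), np.array([0.5])).data) == \
            pytest.approx(np.log(2), abs=1e-6)

    def test_all_masked_errors(self):
        mask = np.ones((1, 3), dtype=bool)
        g = _graph_from_mask(mask, np.random.default_rng(0).random((1, 1, 3)))
        cfg = GCNConfig(seed=0)
        params = init_params(cfg, 1)
        from retinograph.gcn import _forward_scores

        scores = _forward_scores(g, cfg, params)
        codes = np.full(3, UNDEFINED, dtype=np.uint8)
        with pytest.raises(ValueError, match="undefined"):
            combined_loss(scores, codes, cfg)


class TestTrainGcn:
    def _samples(self, n, seed0=0):
        out = []
        for k in range(n):
            rng = np.random.default_rng(seed0 + k)
            mask = np.ones((6, 10), dtype=bool)
            codes = np.zeros((6, 10), dtype=np.uint8)
            codes[:, :5] = ARTERY
            codes[:, 5:] = VEIN
            feats = np.where(codes == ARTERY, 1.0, -1.0)[None] \
                + 0.2 * rng.standard_normal((1, 6, 10))
            g = _graph_from_mask(mask, feats)
            out.append((g, codes[mask]))
        return out

    def test_loss_decreases_majority_of_seeds(self):
        wins = 0
        for seed in range(10):
            samples = self._samples(2, seed0=100 + seed)
            _, trace = train_gcn(samples, GCNConfig(seed=seed), epochs=15)
            wins += trace[-1]["loss"] < trace[0]["loss"]
        assert wins >= 9

    def test_separable_accuracy(self):
        samples = self._samples(3)
        cfg = GCNConfig(seed=0)
        params, _ = train_gcn(samples, cfg, epochs=40)
        g, codes = self._samples(1, seed0=99)[0]
        pred = forward(g, cfg, params)
        assert np.mean(pred.labels == codes) > 0.9

    def test_identical_seeds_identical_traces(self):
        samples = self._samples(1)
        _, t1 = train_gcn(samples, GCNConfig(seed=3), epochs=5)
        _, t2 = train_gcn(samples, GCNConfig(seed=3), epochs=5)
        assert t1 == t2

    def test_empty_input(self):
        with pytest.raises(ValueError):
            train_gcn([], GCNConfig())


class TestLabelsToImage:
    def test_all_artery(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1:3] = True
        g = build_graph(mask)
        from retinograph.gcn import NodePrediction

        pred = NodePrediction(scores=np.tile([1.0, 0.0], (2, 1)),
                              labels=np.full(2, ARTERY, np.uint8))
        img = labels_to_image(pred, g, (4, 4))
        assert (img[mask] == ARTERY).all()
        assert (img[~mask] == BACKGROUND).all()

    def test_round_trip_and_counts(self):
        rng = np.random.default_rng(0)
        mask = rng.random((8, 8)) > 0.5
        g = build_graph(mask)
        labels = rng.choice([ARTERY, VEIN], size=g.n_nodes).astype(np.uint8)
        from retinograph.gcn import NodePrediction

        pred = NodePrediction(scores=np.zeros((g.n_nodes, 2)), labels=labels)
        img = labels_to_image(pred, g, mask.shape)
        np.testing.assert_array_equal(img[g.nodes[:, 0], g.nodes[:, 1]], labels)
        for code in (ARTERY, VEIN):
            assert (img == code).sum() == (labels == code).sum()

    def test_out_of_bounds(self):
        g = build_graph(np.ones((4, 4), dtype=bool))
        from retinograph.gcn import NodePrediction

        pred = NodePrediction(scores=np.zeros((16, 2)),
                              labels=np.full(16, VEIN, np.uint8))
        with pytest.raises(ValueError, match="outside"):
            labels_to_image(pred, g, (3, 4))
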