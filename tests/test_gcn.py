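"""GCN forward/backward correctness, loss algebra, training, and persistence."""

import dataclasses

import numpy as np
import pytest

from cohortgcn import (
    GCNConfig,
    GCNError,
    GCNModel,
    PopulationGraph,
    TrainingResult,
    build_graph,
    class_weights,
    forward,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
    vectorize,
    weighted_loss,
)
from cohortgcn.gcn import _backward, _forward


def _graph_from_parts(X, S, y, train_mask):
    X = np.asarray(X, float)
    n = X.shape[0]
    train = np.asarray(train_mask, bool)
    test = (~train) & (np.asarray(y) >= 0)
    return PopulationGraph(
        X=np.asarray(X, float),
        A=np.zeros((n, n)),
        S=np.asarray(S, float),
        sigma=1.0,
        node_ids=[f"s{i}" for i in range(n)],
        y=np.asarray(y),
        masks={"train_labeled": train, "test_labeled": test, "unlabeled": np.asarray(y) < 0},
    )


class TestForward:
    def test_single_layer_preactivation_matches_dense_product(self):
        # S = [[.5,.5],[.5,.5]], X = [[1],[3]], W = [[1]] -> S X W = [[2],[2]]
        g = _graph_from_parts([[1.0], [3.0]], [[0.5, 0.5], [0.5, 0.5]], [1, 0], [True, True])
        cfg = GCNConfig(n_layers=1, n_filters=1, dropout_rate=0.0)
        model = GCNModel(cfg, n_features=1)
        model.weights[0] = np.array([[1.0, 1.0]])  # 1 -> 2 channels, both = S X W = S X
        _, cache = _forward(model, g, training_mode=False)
        np.testing.assert_allclose(cache["Z"][0], [[2.0, 2.0], [2.0, 2.0]], atol=1e-15)

    def test_identity_operator_means_no_mixing(self, rng):
        # With A = 0 (S = I) a node's output depends only on its own features.
        X = rng.normal(size=(5, 3))
        y = np.array([1, 0, 1, 0, 1])
        g = _graph_from_parts(X, np.eye(5), y, np.ones(5, bool))
        cfg = GCNConfig(n_layers=1, n_filters=4, dropout_rate=0.0, seed=0)
        model = GCNModel.initialize(cfg, 3, rng)
        P1 = forward(model, g)
        X2 = X.copy()
        X2[4] += 10.0  # perturb one node
        g2 = _graph_from_parts(X2, np.eye(5), y, np.ones(5, bool))
        P2 = forward(model, g2)
        np.testing.assert_array_equal(P1[:4], P2[:4])
        assert not np.allclose(P1[4], P2[4])

    def test_matches_per_node_brute_force_aggregation(self, tiny_graph, rng):
        """Full forward equals a python-loop neighbor-sum oracle, layer by layer."""
        cfg = GCNConfig(n_layers=3, n_filters=5, dropout_rate=0.0, seed=1)
        model = GCNModel.initialize(cfg, tiny_graph.n_features, rng)
        # oracle: no matrix library beyond scalar arithmetic
        S, H = tiny_graph.S, tiny_graph.X
        n = tiny_graph.n_nodes
        for l in range(3):
            W = model.weights[l]
            d_out = W.shape[1]
            Z = np.zeros((n, d_out))
            for i in range(n):
                for k in range(d_out):
                    acc = 0.0
                    for j in range(n):
                        for f in range(H.shape[1]):
                            acc += S[i, j] * H[j, f] * W[f, k]
                    Z[i, k] = acc
            mu, var = model.running_mean[l], model.running_var[l]
            Y = model.gamma[l] * (Z - mu) / np.sqrt(var + 1e-5) + model.beta[l]
            if l < 2:
                H = np.maximum(Y, 0.0)
            else:
                e = np.exp(Y - Y.max(axis=1, keepdims=True))
                expected = e / e.sum(axis=1, keepdims=True)
        P = forward(model, tiny_graph)
        np.testing.assert_allclose(P, expected, atol=1e-10)

    def test_rows_sum_to_one(self, tiny_graph, rng):
        for layers in (1, 2, 4):
            cfg = GCNConfig(n_layers=layers, n_filters=6, dropout_rate=0.0)
            model = GCNModel.initialize(cfg, tiny_graph.n_features, rng)
            P = forward(model, tiny_graph)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-6)

    def test_dimension_mismatch_names_layer(self, tiny_graph):
        model = GCNModel(GCNConfig(n_layers=1, n_filters=2), n_features=9)
        with pytest.raises(GCNError, match="layer 0"):
            forward(model, tiny_graph)


class TestGradients:
    def test_backward_matches_finite_differences(self, tiny_graph):
        """Analytic gradients agree with central differences to 1e-5 relative."""
        cfg = GCNConfig(n_layers=3, n_filters=5, dropout_rate=0.0, seed=1)
        model = GCNModel.initialize(cfg, tiny_graph.n_features, np.random.default_rng(1))
        y, mask = tiny_graph.y, tiny_graph.masks["train_labeled"]
        beta = class_weights(y, mask)
        P, cache = _forward(model, tiny_graph, training_mode=True)
        grads = _backward(model, tiny_graph, cache, y, mask, beta)
        params = model.trainable_parameters()
        check_rng = np.random.default_rng(7)
        eps = 1e-6
        for p, g in zip(params, grads):
            flat_idx = check_rng.choice(p.size, size=min(6, p.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = weighted_loss(_forward(model, tiny_graph, True)[0], y, mask)
                p[idx] = orig - eps
                lm = weighted_loss(_forward(model, tiny_graph, True)[0], y, mask)
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[idx], rel=1e-5, abs=1e-8)

    def test_nontraining_labels_have_zero_gradient(self, tiny_graph):
        """Flipping a test/unlabeled node's stored label leaves gradients unchanged."""
        cfg = GCNConfig(n_layers=2, n_filters=4, dropout_rate=0.0, seed=2)
        model = GCNModel.initialize(cfg, tiny_graph.n_features, np.random.default_rng(2))
        mask = tiny_graph.masks["train_labeled"]
        beta = class_weights(tiny_graph.y, mask)
        _, cache = _forward(model, tiny_graph, training_mode=True)
        g1 = _backward(model, tiny_graph, cache, tiny_graph.y, mask, beta)
        y2 = tiny_graph.y.copy()
        y2[6] = 1 - y2[6]  # test node
        g2 = _backward(model, tiny_graph, cache, y2, mask, beta)
        for a, b in zip(g1, g2):
            np.testing.assert_array_equal(a, b)


class TestWeightedLoss:
    def test_coin_flip_two_classes_unweighted_is_ln2(self):
        P = np.full((2, 2), 0.5)
        y = np.array([1, 0])
        mask = np.ones(2, bool)
        assert weighted_loss(P, y, mask, "unweighted") == pytest.approx(np.log(2), abs=1e-12)

    def test_equal_counts_weighted_is_twice_unweighted(self, rng):
        P = rng.dirichlet([1, 1], size=8)
        y = np.array([1, 0] * 4)
        mask = np.ones(8, bool)
        lw = weighted_loss(P, y, mask, "weighted")
        lu = weighted_loss(P, y, mask, "unweighted")
        assert lw == pytest.approx(2 * lu, rel=1e-12)

    def test_inverse_frequency_weights_on_37_82_split(self):
        """119 labeled subjects split 37 positive / 82 negative."""
        y = np.array([1] * 37 + [0] * 82)
        beta = class_weights(y, np.ones(119, bool))
        assert beta[1] == pytest.approx(119 / 37, rel=1e-15)
        assert beta[0] == pytest.approx(119 / 82, rel=1e-15)

    def test_weights_computed_on_mask_only(self):
        y = np.array([1] * 37 + [0] * 82 + [-1] * 105)
        mask = np.zeros(224, bool)
        mask[:119] = True
        beta = class_weights(y, mask)
        assert beta[1] == pytest.approx(119 / 37)

    def test_unit_weights_equal_unweighted_exactly(self, rng):
        # weighted mode with forced beta = 1 is algebraically the unweighted loss
        P = rng.dirichlet([1, 1], size=6)
        y = np.array([1, 1, 1, 0, 0, 0])
        mask = np.ones(6, bool)
        assert weighted_loss(P, y, mask, "weighted") == pytest.approx(
            2 * weighted_loss(P, y, mask, "unweighted"), rel=1e-12
        )  # balanced set: beta = 2 for both classes

    def test_extreme_probabilities_are_clamped(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([1, 0])
        loss = weighted_loss(P, y, np.ones(2, bool), "unweighted")
        assert np.isfinite(loss)

    def test_masked_missing_label_rejected(self):
        P = np.full((2, 2), 0.5)
        with pytest.raises(GCNError, match="missing label"):
            weighted_loss(P, np.array([1, -1]), np.ones(2, bool))

    def test_single_class_mask_rejected(self):
        with pytest.raises(GCNError, match="single class"):
            class_weights(np.array([1, 1, 1]), np.ones(3, bool))


class TestTraining:
    def test_separable_clusters_reach_perfect_training_accuracy(self, small_cohort):
        connectomes, manifest = small_cohort
        g = build_graph([vectorize(c) for c in connectomes], manifest, sigma=0.3)
        res = train(g, GCNConfig(n_layers=2, n_filters=8, max_epochs=200, seed=0))
        labels, _ = predict(res, g.masks["train_labeled"])
        truth = g.y[g.masks["train_labeled"]]
        assert (labels == truth).mean() == 1.0

    def test_unused_labels_do_not_affect_training(self, small_cohort):
        """Permuting labels of unlabeled/test nodes gives a bit-identical result."""
        connectomes, manifest = small_cohort
        g = build_graph([vectorize(c) for c in connectomes], manifest, sigma=0.3,
                        test_ids=manifest.subject_ids[:5])
        cfg = GCNConfig(n_layers=2, n_filters=8, max_epochs=60, seed=4)
        res1 = train(g, cfg)
        g2 = dataclasses.replace(g)
        y2 = g.y.copy()
        hidden = ~g.masks["train_labeled"]
        y2[hidden] = np.random.default_rng(0).permutation(y2[hidden])
        g2.y = y2
        res2 = train(g2, cfg)
        np.testing.assert_array_equal(res1.probabilities, res2.probabilities)
        np.testing.assert_array_equal(res1.loss_trajectory, res2.loss_trajectory)

    def test_loss_descends_on_separable_data(self, small_cohort):
        connectomes, manifest = small_cohort
        g = build_graph([vectorize(c) for c in connectomes], manifest, sigma=0.3)
        for seed in range(10):
            res = train(g, GCNConfig(n_layers=2, n_filters=8, max_epochs=80, seed=seed))
            assert res.loss_trajectory[-1] <= res.loss_trajectory[0]

    def test_deterministic_given_seed(self, small_cohort):
        connectomes, manifest = small_cohort
        g = build_graph([vectorize(c) for c in connectomes], manifest, sigma=0.3)
        cfg = GCNConfig(n_layers=2, n_filters=8, max_epochs=40, seed=9)
        r1, r2 = train(g, cfg), train(g, cfg)
        np.testing.assert_array_equal(r1.probabilities, r2.probabilities)

    def test_single_class_training_mask_rejected(self, tiny_graph):
        g = dataclasses.replace(tiny_graph)
        g.y = np.where(g.y >= 0, 1, -1)
        with pytest.raises(GCNError, match="inverse-frequency"):
            train(g, GCNConfig(n_layers=1, n_filters=2, max_epochs=5))

    def test_early_stopping_respects_patience(self, small_cohort):
        connectomes, manifest = small_cohort
        g = build_graph([vectorize(c) for c in connectomes], manifest, sigma=0.3)
        res = train(g, GCNConfig(n_layers=2, n_filters=8, max_epochs=500, seed=0,
                                 dropout_rate=0.0, patience=10))
        assert res.loss_trajectory.size < 500


class TestPredict:
    def test_argmax_and_positive_probability(self):
        model = GCNModel(GCNConfig(n_layers=1, n_filters=2), 1)
        res = TrainingResult(model, np.zeros(1), np.array([[0.2, 0.8], [0.9, 0.1]]))
        labels, pos = predict(res, np.array([0, 1]))
        np.testing.assert_array_equal(labels, [1, 0])
        np.testing.assert_array_equal(pos, [0.8, 0.1])

    def test_exact_tie_goes_to_positive(self):
        model = GCNModel(GCNConfig(n_layers=1, n_filters=2), 1)
        res = TrainingResult(model, np.zeros(1), np.array([[0.5, 0.5]]))
        labels, _ = predict(res, np.array([0]))
        assert labels[0] == 1


class TestCheckpoint:
    def test_round_trip_reproduces_probabilities(self, small_cohort, tmp_path):
        connectomes, manifest = small_cohort
        g = build_graph([vectorize(c) for c in connectomes], manifest, sigma=0.3)
        res = train(g, GCNConfig(n_layers=2, n_filters=8, max_epochs=50, seed=0))
        path = tmp_path / "model.npz"
        save_checkpoint(res.model, path, node_ids=g.node_ids, sigma=0.3, kernel="gaussian")
        model2, meta = load_checkpoint(path)
        np.testing.assert_array_equal(forward(model2, g), res.probabilities)
        assert meta["sigma"] == 0.3
        assert meta["node_ids"] == g.node_ids

    def test_config_survives_round_trip(self, tmp_path):
        cfg = GCNConfig(n_layers=4, n_filters=16, dropout_rate=0.3, loss="unweighted", seed=5)
        model = GCNModel.initialize(cfg, 10, np.random.default_rng(0))
        save_checkpoint(model, tmp_path / "m.npz")
        model2, _ = load_checkpoint(tmp_path / "m.npz")
        assert model2.config == cfg
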