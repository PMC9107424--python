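"""RegGNN architecture: preprocessing, forward pass, gradients, training."""

import numpy as np
import pytest

from reggnn.cohort import CohortSpec, generate_cohort
from reggnn.exceptions import ConfigurationError, ValidationError
from reggnn.network import (
    PreprocessedGraph,
    RegGNNConfig,
    RegGNNParameters,
    _loss_and_grads,
    average_region_ranking,
    forward,
    gcn_layer,
    load_parameters,
    normalized_adjacency,
    predict,
    preprocess_for_gnn,
    region_weights,
    save_parameters,
    train,
)


def overfit_config(d, seed=0, epochs=500):
    """Capacity-check settings: no regularization, convergent learning rate."""
    return RegGNNConfig(d=d, epochs=epochs, seed=seed, dropout=0.0, weight_decay=0.0, learning_rate=0.01)


def synthetic_graphs(n=5, d=20, seed=0, cfg=None):
    spec = CohortSpec(n_subjects=n, d=d, n_clusters=1, score_sd=12.056, seed=seed)
    coh = generate_cohort(spec)
    cfg = cfg or RegGNNConfig(d=d)
    return [preprocess_for_gnn(s.connectome, cfg, subject_id=s.id, score=s.score) for s in coh.subjects]


class TestPreprocess:
    def test_negative_correlations_zeroed(self):
        C = np.array([[1.0, -0.5], [-0.5, 1.0]])
        g = preprocess_for_gnn(C, RegGNNConfig(d=2))
        np.testing.assert_allclose(g.adjacency, np.eye(2) + 1e-10 * np.eye(2), atol=1e-9)

    def test_identity_connectome_normalizes_to_identity(self):
        g = preprocess_for_gnn(np.eye(2), RegGNNConfig(d=2))
        np.testing.assert_allclose(g.norm_adjacency, np.eye(2), atol=1e-9)

    def test_two_node_normalization_by_hand(self):
        np.testing.assert_allclose(
            normalized_adjacency(np.array([[0.0, 1.0], [1.0, 0.0]])),
            [[0.5, 0.5], [0.5, 0.5]],
        )

    def test_eigenvalue_clamping_mode_gives_nonnegative_adjacency(self, rng):
        from conftest import random_spd

        P = random_spd(5, rng, 0.2)
        D = 1.0 / np.sqrt(np.diag(P))
        C = P * D[:, None] * D[None, :]
        np.fill_diagonal(C, 1.0)
        g = preprocess_for_gnn(C, RegGNNConfig(d=5, neg_handling="clamp_eigenvalues"))
        assert g.adjacency.min() >= 0.0

    def test_spectral_radius_bounded(self, rng):
        for _ in range(10):
            A = np.abs(rng.standard_normal((6, 6)))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            Ah = normalized_adjacency(A)
            np.testing.assert_allclose(Ah, Ah.T, atol=1e-12)
            assert np.abs(np.linalg.eigvalsh(Ah)).max() <= 1.0 + 1e-8


class TestForward:
    def worked_example(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        g = PreprocessedGraph("x", A, normalized_adjacency(A), 0.0)
        params = RegGNNParameters(
            W1=np.eye(2), W2=np.array([[1.0], [1.0]]), fc_w=np.array([1.0, 1.0]), fc_b=0.0
        )
        return g, params, RegGNNConfig(d=2, hidden=2, dropout=0.0)

    def test_hand_computed_output(self):
        g, params, cfg = self.worked_example()
        assert forward(g, params, cfg) == pytest.approx(2.0, abs=1e-12)

    def test_zero_parameters_output_bias(self):
        g, params, cfg = self.worked_example()
        zero = RegGNNParameters(np.zeros((2, 2)), np.zeros((2, 1)), np.zeros(2), 3.25)
        assert forward(g, zero, cfg) == 3.25

    def test_gcn_layer_examples(self):
        Ah = np.array([[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(gcn_layer(np.eye(2), Ah, np.array([[1.0], [1.0]])), [[1.0], [1.0]])
        np.testing.assert_allclose(gcn_layer(np.eye(2), Ah, np.zeros((2, 3))), np.zeros((2, 3)))
        np.testing.assert_allclose(gcn_layer(np.eye(2), Ah, -np.ones((2, 2))), np.zeros((2, 2)))

    def test_gcn_layer_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            gcn_layer(np.eye(3), np.eye(2), np.eye(3))

    def test_eval_mode_deterministic(self):
        graphs = synthetic_graphs(n=1)
        cfg = RegGNNConfig(d=20, dropout=0.5)
        params, _ = train(graphs, RegGNNConfig(d=20, epochs=2))
        a = forward(graphs[0], params, cfg, training_mode=False)
        b = forward(graphs[0], params, cfg, training_mode=False)
        assert a == b

    def test_permutation_equivariance(self, rng):
        d = 5
        A = np.abs(rng.standard_normal((d, d)))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        perm = rng.permutation(d)
        Pi = np.eye(d)[perm]
        params = RegGNNParameters(
            W1=rng.standard_normal((d, 3)),
            W2=rng.standard_normal((3, 1)),
            fc_w=rng.standard_normal(d),
            fc_b=0.7,
        )
        cfg = RegGNNConfig(d=d, hidden=3, dropout=0.0)
        g = PreprocessedGraph("a", A, normalized_adjacency(A), 0.0)
        gp = PreprocessedGraph("b", Pi @ A @ Pi.T, normalized_adjacency(Pi @ A @ Pi.T), 0.0)
        permuted = RegGNNParameters(Pi @ params.W1, params.W2, Pi @ params.fc_w, params.fc_b)
        assert forward(gp, permuted, cfg) == pytest.approx(forward(g, params, cfg), abs=1e-10)


class TestGradients:
    def test_finite_difference_check(self, rng):
        d = 4
        cfg = RegGNNConfig(d=d, hidden=3, dropout=0.0, weight_decay=0.0005)
        graphs = synthetic_graphs(n=3, d=d, cfg=cfg)
        params = RegGNNParameters(
            W1=rng.standard_normal((d, 3)) * 0.3,
            W2=np.abs(rng.standard_normal((3, 1))) * 0.3,
            fc_w=rng.standard_normal(d) * 0.3,
            fc_b=100.0,
        )
        masks = [None] * len(graphs)
        loss, _, grads = _loss_and_grads(params, graphs, cfg, masks)
        eps = 1e-6

        def loss_at(p):
            return _loss_and_grads(p, graphs, cfg, masks)[0]

        for key in ("W1", "W2", "fc_w"):
            arr = getattr(params, key)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                plus, minus = params.copy(), params.copy()
                getattr(plus, key)[idx] += eps
                getattr(minus, key)[idx] -= eps
                num = (loss_at(plus) - loss_at(minus)) / (2 * eps)
                ana = grads[key][idx]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), (key, idx)
        plus, minus = params.copy(), params.copy()
        plus.fc_b += eps
        minus.fc_b -= eps
        num = (loss_at(plus) - loss_at(minus)) / (2 * eps)
        assert abs(num - grads["fc_b"]) <= 1e-4 * max(1.0, abs(num))


class TestTraining:
    def test_loss_history_length_and_reproducibility(self):
        graphs = synthetic_graphs(n=4)
        cfg = RegGNNConfig(d=20, epochs=7, seed=3)
        p1, h1 = train(graphs, cfg)
        p2, h2 = train(graphs, cfg)
        assert len(h1) == 7
        np.testing.assert_array_equal(p1.W1, p2.W1)
        np.testing.assert_array_equal(p1.fc_w, p2.fc_w)
        assert h1 == h2

    def test_zero_learning_rate_keeps_initialization(self):
        graphs = synthetic_graphs(n=3)
        cfg = RegGNNConfig(d=20, epochs=5, learning_rate=0.0, weight_decay=0.0, dropout=0.0, seed=1)
        params, _ = train(graphs, cfg)
        from reggnn.network import _init_parameters

        rng = np.random.default_rng(1)
        init = _init_parameters(cfg, float(np.mean([g.score for g in graphs])), rng)
        np.testing.assert_array_equal(params.W1, init.W1)
        np.testing.assert_array_equal(params.W2, init.W2)

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValidationError):
            train([], RegGNNConfig(d=2))

    def test_dimension_mismatch_rejected(self):
        graphs = synthetic_graphs(n=2, d=6, cfg=RegGNNConfig(d=6))
        with pytest.raises(ConfigurationError):
            train(graphs, RegGNNConfig(d=7))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_overfits_five_samples(self, seed):
        cfg = overfit_config(d=20, seed=seed)
        graphs = synthetic_graphs(n=5, d=20, seed=0, cfg=cfg)
        params, hist = train(graphs, cfg)
        pred = predict(params, graphs, cfg)
        truth = np.array([g.score for g in graphs])
        assert np.mean(np.abs(pred - truth)) < 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_windowed_loss_decreases_until_convergence(self, seed):
        cfg = overfit_config(d=20, seed=seed)
        graphs = synthetic_graphs(n=5, d=20, seed=0, cfg=cfg)
        _, hist = train(graphs, cfg)
        windows = np.asarray(hist).reshape(-1, 50).mean(axis=1)
        # strictly decreasing while above 1 MSE; below that Adam dithers
        above = windows[windows > 1.0]
        assert np.all(np.diff(above) < 0)
        assert windows[-1] < 1.0


class TestPredictionAndWeights:
    def test_predict_matches_forward_loop(self):
        graphs = synthetic_graphs(n=3)
        cfg = RegGNNConfig(d=20, epochs=2)
        params, _ = train(graphs, cfg)
        out = predict(params, graphs, cfg)
        np.testing.assert_array_equal(out, [forward(g, params, cfg) for g in graphs])

    def test_region_weight_ranking(self):
        params = RegGNNParameters(np.zeros((3, 2)), np.zeros((2, 1)), np.array([0.1, -0.9, 0.5]), 0.0)
        assert [roi for roi, _ in region_weights(params)] == [1, 2, 0]

    def test_tied_weights_keep_index_order(self):
        params = RegGNNParameters(np.zeros((3, 2)), np.zeros((2, 1)), np.array([0.5, 0.5, 0.5]), 0.0)
        assert [roi for roi, _ in region_weights(params)] == [0, 1, 2]

    def test_averaging_identical_rankings_is_identity(self):
        params = RegGNNParameters(np.zeros((3, 2)), np.zeros((2, 1)), np.array([0.2, 0.9, 0.4]), 0.0)
        avg = average_region_ranking([params, params])
        assert [roi for roi, _ in avg] == [roi for roi, _ in region_weights(params)]

    def test_parameter_serialization_round_trip(self, tmp_path):
        graphs = synthetic_graphs(n=2)
        cfg = RegGNNConfig(d=20, epochs=2)
        params, _ = train(graphs, cfg)
        path = tmp_path / "weights.npz"
        save_parameters(params, path)
        loaded = load_parameters(path)
        np.testing.assert_array_equal(loaded.W1, params.W1)
        np.testing.assert_array_equal(loaded.fc_w, params.fc_w)
        assert loaded.fc_b == params.fc_b
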