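"""Unit and property tests for the dual AE/GAE annotator."""

import numpy as np
import pytest
import scipy.sparse as sp

from sttransfer._nn import Tensor
from sttransfer.annotator import (AnnotatorConfig, AnnotatorState, _Net,
                                  adjacency_bce_exact, adjacency_bce_sampled,
                                  ae_decode, ae_encode, combine_latent,
                                  graph_decode, graph_encode, loss_ae, loss_gae,
                                  loss_ssl, predict_labels, total_loss,
                                  train_annotator)
from sttransfer.graph import SpatialGraph, build_graph, normalize_adjacency
from sttransfer.teacher import TeacherDistribution
from sttransfer.vae import LatentEmbedding


def make_state(d=6, n_classes=3, **cfg_kwargs) -> AnnotatorState:
    cfg = AnnotatorConfig(k1=8, k=4, seed=0, **cfg_kwargs)
    net = _Net(d, n_classes, cfg)
    state = AnnotatorState(net, [f"t{i}" for i in range(n_classes)], cfg, d)
    state.trained = True
    return state


def random_graph(n, k=3, seed=0):
    coords = np.random.default_rng(seed).uniform(0, 10, size=(n, 2))
    return normalize_adjacency(build_graph(coords, k_neighbors=k))


class TestForwardPieces:
    def test_ae_encode_eval_mode_deterministic_and_shaped(self):
        state = make_state()
        x = np.random.default_rng(0).normal(size=(50, 6))
        out1 = ae_encode(x, state, training=False)
        out2 = ae_encode(x, state, training=False)
        assert out1.shape == (50, 4)
        np.testing.assert_array_equal(out1, out2)

    def test_ae_decode_shape_and_zero_input_gives_bias(self):
        state = make_state()
        out = ae_decode(np.zeros((5, 4)), state, training=False)
        assert out.shape == (5, 6)
        # zero the decoder weights: output must be the final bias broadcast
        state.net.dec2.weight.data[:] = 0.0
        state.net.dec2.bias.data[:] = 7.5
        out = ae_decode(np.random.default_rng(1).normal(size=(5, 4)), state)
        np.testing.assert_allclose(out, 7.5)

    def test_dimension_mismatch_errors(self):
        state = make_state()
        with pytest.raises(ValueError, match="dims"):
            ae_encode(np.zeros((3, 5)), state)
        with pytest.raises(ValueError, match="dims"):
            ae_decode(np.zeros((3, 5)), state)

    def test_graph_encode_identity_graph_matches_dense_oracle(self):
        # A_norm = I: S = W2^T relu(W1^T x) exactly (dropout off in eval)
        state = make_state()
        n = 10
        g = SpatialGraph(adjacency=sp.csr_matrix((n, n)), theta=1.0, k_neighbors=1)
        normalize_adjacency(g)  # isolated nodes -> identity normalization
        x = np.random.default_rng(2).normal(size=(n, 4))
        out = graph_encode(x, g, state, training=False)
        w1, w2 = state.net.gc1.weight.data, state.net.gc2.weight.data
        expected = np.maximum(x @ w1, 0.0) @ w2
        np.testing.assert_allclose(out, expected, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_sparse_conv_equals_dense_oracle_on_random_graphs(self, seed):
        state = make_state()
        n = 30
        g = random_graph(n, k=4, seed=seed)
        x = np.random.default_rng(seed + 100).normal(size=(n, 4))
        out = graph_encode(x, g, state, training=False)
        a_dense = g.normalized.toarray()
        w1, w2 = state.net.gc1.weight.data, state.net.gc2.weight.data
        expected = a_dense @ (np.maximum(a_dense @ (x @ w1), 0.0) @ w2)
        assert np.abs(out - expected).max() < 1e-6

    def test_graph_size_mismatch_errors(self):
        state = make_state()
        g = random_graph(8)
        with pytest.raises(ValueError, match="nodes"):
            graph_encode(np.zeros((9, 4)), g, state)

    def test_combine_latent_sum_and_commutativity(self):
        x = np.random.default_rng(0).normal(size=(4, 3))
        s = np.random.default_rng(1).normal(size=(4, 3))
        np.testing.assert_array_equal(combine_latent(x, np.zeros_like(x)), x)
        np.testing.assert_array_equal(combine_latent(np.zeros_like(s), s), s)
        np.testing.assert_array_equal(combine_latent(x, s), combine_latent(s, x))
        with pytest.raises(ValueError, match="shape"):
            combine_latent(x, s[:2])

    def test_graph_decode_closed_forms(self):
        z = np.zeros((3, 2))
        np.testing.assert_allclose(graph_decode(z), 0.5)
        z = np.eye(2)  # orthonormal rows
        a = graph_decode(z)
        assert a[0, 1] == pytest.approx(0.5, abs=1e-9)
        assert a[0, 0] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-6)  # 0.731059
        z = np.random.default_rng(0).normal(size=(6, 3))
        np.testing.assert_array_equal(graph_decode(z), graph_decode(z).T)


class TestLosses:
    def test_loss_ae_closed_forms(self):
        assert float(loss_ae([[1.0, 2.0]], [[1.0, 2.0]]).data) == 0.0
        assert float(loss_ae([[0.0]], [[2.0]]).data) == pytest.approx(4.0, abs=1e-12)

    def test_loss_ae_quadratic_homogeneity(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(5, 4))
        r = rng.normal(size=(5, 4))
        base = float(loss_ae(t, t + r).data)
        scaled = float(loss_ae(t, t + 3.0 * r).data)
        assert scaled == pytest.approx(9.0 * base, rel=1e-12)

    def test_loss_gae_at_half_is_ln2(self):
        a = np.full((4, 4), 0.5)
        assert float(loss_gae(a, a).data) == pytest.approx(np.log(2), abs=1e-9)

    def test_loss_gae_vanishes_at_confident_match(self):
        a = (np.random.default_rng(0).random((5, 5)) > 0.5).astype(float)
        a_prime = np.clip(a, 1e-9, 1 - 1e-9)
        assert float(loss_gae(a, a_prime).data) < 1e-6

    def test_loss_ssl_hand_case(self):
        d = np.array([[1.0, 0.0]])
        p = np.array([[0.5, 0.5]])
        assert float(loss_ssl(d, p).data) == pytest.approx(0.5 * np.log(2), abs=1e-9)

    def test_loss_ssl_minimized_at_p_equals_d(self):
        rng = np.random.default_rng(1)
        d = rng.dirichlet(np.ones(4), size=6)
        at_d = float(loss_ssl(d, d).data)
        for _ in range(20):
            other = rng.dirichlet(np.ones(4), size=6)
            assert float(loss_ssl(d, other).data) >= at_d - 1e-12

    def test_total_loss_weighting(self):
        cfg = AnnotatorConfig(w_dae=1, w_gae=0, w_cls=0)
        assert float(total_loss(0.7, 123.0, 456.0, cfg).data) == pytest.approx(0.7)
        cfg = AnnotatorConfig(w_dae=1, w_gae=1, w_cls=1)
        assert float(total_loss(0.2, 0.3, 0.5, cfg).data) == pytest.approx(1.0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            AnnotatorConfig(w_dae=0, w_gae=0, w_cls=0)

    def test_zero_weight_decouples_sub_loss(self):
        cfg = AnnotatorConfig(w_dae=1, w_gae=0, w_cls=2)
        a = float(total_loss(0.4, 0.1, 0.3, cfg).data)
        b = float(total_loss(0.4, 99.0, 0.3, cfg).data)
        assert a == b

    def test_loss_gradients_match_finite_differences(self):
        """Autodiff gradients of each loss agree with central differences."""
        rng = np.random.default_rng(3)
        n, d, c = 5, 4, 3
        tti = rng.normal(size=(n, d))
        g = random_graph(n, k=2, seed=3)
        teacher = rng.dirichlet(np.ones(c), size=n)

        def check(fn, x0):
            x = Tensor(x0.copy(), requires_grad=True)
            fn(x).backward()
            grad = x.grad.copy()
            eps = 1e-6
            for idx in [(0, 0), (2, 1), (x0.shape[0] - 1, x0.shape[1] - 1)]:
                x.data[idx] += eps
                up = float(fn(Tensor(x.data)).data)
                x.data[idx] -= 2 * eps
                dn = float(fn(Tensor(x.data)).data)
                x.data[idx] += eps
                fd = (up - dn) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

        check(lambda x: loss_ae(tti, x), tti + rng.normal(size=(n, d)))
        check(lambda z: adjacency_bce_exact(z, g), rng.normal(size=(n, d)))
        check(lambda p: loss_ssl(teacher, p.softmax(axis=1)),
              rng.normal(size=(n, c)))


class TestAdjacencySampling:
    def test_sampled_bce_unbiased_for_exact_balanced_loss(self):
        """Monte-Carlo mean of the subsampled estimator matches the exact
        balanced double sum within 3 standard errors (100 seeds)."""
        g = random_graph(20, k=3, seed=9)
        z = Tensor(np.random.default_rng(10).normal(size=(20, 4)))
        exact = float(adjacency_bce_exact(z, g).data)
        draws = np.array([
            float(adjacency_bce_sampled(z, g, np.random.default_rng(s)).data)
            for s in range(100)])
        se = draws.std(ddof=1) / 10.0
        assert abs(draws.mean() - exact) < 3 * max(se, 1e-12)


@pytest.fixture(scope="module")
def toy_problem():
    """Two spatially separated clusters with matching teacher signal."""
    rng = np.random.default_rng(42)
    n_half = 30
    coords = np.concatenate([rng.uniform(0, 1, size=(n_half, 2)),
                             rng.uniform(2, 3, size=(n_half, 2))])
    emb = np.concatenate([rng.normal(0, 0.3, size=(n_half, 6)),
                          rng.normal(2, 0.3, size=(n_half, 6))])
    d = np.zeros((2 * n_half, 2))
    d[:n_half, 0] = 0.9
    d[:n_half, 1] = 0.1
    d[n_half:, 0] = 0.1
    d[n_half:, 1] = 0.9
    tti = LatentEmbedding(emb, [f"c{i}" for i in range(2 * n_half)], "spatial")
    g = normalize_adjacency(build_graph(coords, k_neighbors=5))
    teacher = TeacherDistribution(d, ["alpha", "beta"],
                                  [f"c{i}" for i in range(2 * n_half)])
    return tti, g, teacher


class TestTraining:

    def test_training_reduces_total_loss(self, toy_problem):
        tti, g, teacher = toy_problem
        cfg = AnnotatorConfig(k1=16, k=6, epochs=60, seed=0)
        state = train_annotator(tti, g, teacher, cfg)
        assert state.loss_history[-1]["total"] < state.loss_history[0]["total"]

    def test_same_seed_gives_identical_parameters(self, toy_problem):
        tti, g, teacher = toy_problem
        cfg = AnnotatorConfig(k1=16, k=6, epochs=10, seed=5)
        s1 = train_annotator(tti, g, teacher, cfg)
        s2 = train_annotator(tti, g, teacher, cfg)
        for key, arr in s1.net.state_arrays().items():
            np.testing.assert_array_equal(arr, s2.net.state_arrays()[key])

    def test_zero_cls_weight_leaves_student_untouched(self, toy_problem):
        tti, g, teacher = toy_problem
        cfg = AnnotatorConfig(k1=16, k=6, epochs=5, w_cls=0.0, seed=1)
        state = train_annotator(tti, g, teacher, cfg)
        fresh = _Net(6, 2, cfg)
        np.testing.assert_array_equal(state.net.student.weight.data,
                                      fresh.student.weight.data)

    def test_predictions_recover_spatial_clusters(self, toy_problem):
        tti, g, teacher = toy_problem
        cfg = AnnotatorConfig(k1=16, k=6, epochs=120, seed=0)
        state = train_annotator(tti, g, teacher, cfg)
        labels, probs = predict_labels(state, tti, g)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (labels[:30] == "alpha").mean() > 0.9
        assert (labels[30:] == "beta").mean() > 0.9
        labels2, _ = predict_labels(state, tti, g)
        np.testing.assert_array_equal(labels, labels2)

    def test_untrained_state_refuses_to_predict(self, toy_problem):
        tti, g, teacher = toy_problem
        cfg = AnnotatorConfig(k1=16, k=6)
        state = AnnotatorState(_Net(6, 2, cfg), ["a", "b"], cfg, 6)
        with pytest.raises(ValueError, match="trained"):
            predict_labels(state, tti, g)

    def test_size_mismatch_errors(self, toy_problem):
        tti, g, teacher = toy_problem
        bad = LatentEmbedding(tti.values[:10], tti.cell_ids[:10], "spatial")
        with pytest.raises(ValueError, match="size mismatch"):
            train_annotator(bad, g, teacher, AnnotatorConfig(k1=16, k=6, epochs=1))

    def test_state_round_trips_through_disk(self, toy_problem, tmp_path):
        tti, g, teacher = toy_problem
        cfg = AnnotatorConfig(k1=16, k=6, epochs=5, seed=2)
        state = train_annotator(tti, g, teacher, cfg)
        state.save(tmp_path / "annot")
        back = AnnotatorState.load(tmp_path / "annot")
        l1, p1 = predict_labels(state, tti, g)
        l2, p2 = predict_labels(back, tti, g)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
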