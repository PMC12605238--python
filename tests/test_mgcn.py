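"""Spectral-GCN tests: Laplacian construction, the Chebyshev layer against
a dense spectral oracle, gradients against finite differences, and
training behaviour."""

import numpy as np
import pytest

from cogmi.brain_networks import AdjacencyMatrix, DomainGraph, NodeFeatureMatrix
from cogmi.mgcn import (
    MGCNParams, TrainConfig, _backward, _forward, _loss, cheb_graph_conv,
    forward, init_params, normalized_laplacian, params_digest, prepare_batch,
    predict_trials, train_mgcn,
)


def random_connected_adjacency(rng, n):
    """Random symmetric weighted adjacency in [0,1] with no isolated node."""
    a = rng.uniform(0.05, 1.0, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


def dense_spectral_conv(a, x, w):
    """Oracle: first-order filter g(lambda) = 1 - lambda applied in the
    eigenbasis of the renormalized graph's normalized Laplacian equals the
    propagation-rule convolution."""
    n = len(a)
    a_t = a + np.eye(n)
    d_inv_sqrt = 1.0 / np.sqrt(a_t.sum(axis=1))
    l_norm = np.eye(n) - d_inv_sqrt[:, None] * a_t * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(l_norm)
    g = np.diag(1.0 - vals)
    return vecs @ g @ vecs.T @ x @ w


def make_triple(rng, s=6, label=None, scale=1.0):
    """Random (time, frequency, spatial) triple with controllable scale."""
    dims = {"time": 40, "frequency": 4, "spatial": 1}
    graphs = []
    for domain, f in dims.items():
        a = random_connected_adjacency(rng, s) * min(scale, 1.0)
        np.fill_diagonal(a, 1.0)
        x = rng.standard_normal((s, f)) * scale
        ann = {} if label is None else {"label": label}
        graphs.append(DomainGraph(NodeFeatureMatrix(x, domain),
                                  AdjacencyMatrix(a, domain), ann))
    return tuple(graphs)


class TestLaplacian:
    def test_path_graph_by_hand(self):
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        op = normalized_laplacian(a)
        assert np.allclose(np.diag(op.D), [1, 2, 1])
        assert np.allclose(op.L, [[1, -1, 0], [-1, 2, -1], [0, -1, 1]])

    def test_k3_eigenvalues(self):
        """Complete graph on 3 nodes: normalized-Laplacian spectrum
        {0, 1.5, 1.5} (eigensolve oracle)."""
        a = np.ones((3, 3)) - np.eye(3)
        op = normalized_laplacian(a)
        assert np.allclose(np.sort(np.linalg.eigvalsh(op.L_norm)),
                           [0.0, 1.5, 1.5], atol=1e-10)

    def test_spectrum_bounds_and_kernel(self, rng):
        for n in (4, 7):
            a = random_connected_adjacency(rng, n)
            op = normalized_laplacian(a)
            vals = np.linalg.eigvalsh(op.L_norm)
            assert vals.min() > -1e-8
            assert vals.max() < 2 + 1e-8
            assert abs(vals.min()) < 1e-8  # connected => 0 in the spectrum
            assert np.allclose(op.P, op.P.T, atol=1e-10)

    def test_isolated_node_named(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            normalized_laplacian(a)


class TestChebLayer:
    def test_identity_adjacency_passthrough(self):
        """A = I gives propagation P = I, so with W = I the layer is the
        identity map."""
        op = normalized_laplacian(np.eye(5))
        x = np.arange(20.0).reshape(5, 4)
        out = cheb_graph_conv(x, op, [np.eye(4)], K=1)
        assert np.allclose(out, x)

    def test_matches_dense_spectral_oracle(self, rng):
        for n in (3, 5, 8):
            a = random_connected_adjacency(rng, n)
            x = rng.standard_normal((n, 4))
            w = rng.standard_normal((4, 3))
            op = normalized_laplacian(a)
            got = cheb_graph_conv(x, op, [w], K=1)
            want = dense_spectral_conv(a, x, w)
            assert np.allclose(got, want, atol=1e-6)

    def test_linear_in_weights(self, rng):
        a = random_connected_adjacency(rng, 4)
        op = normalized_laplacian(a)
        x = rng.standard_normal((4, 3))
        w = rng.standard_normal((3, 2))
        assert np.allclose(cheb_graph_conv(x, op, [2 * w], K=1),
                           2 * cheb_graph_conv(x, op, [w], K=1))

    def test_k2_needs_two_weights(self, rng):
        op = normalized_laplacian(random_connected_adjacency(rng, 4))
        x = rng.standard_normal((4, 3))
        with pytest.raises(ValueError):
            cheb_graph_conv(x, op, [np.eye(3)], K=2)
        out = cheb_graph_conv(x, op, [np.eye(3), np.eye(3)], K=2)
        assert out.shape == (4, 3)


class TestForward:
    def test_probabilities_normalized(self, rng):
        triples = [make_triple(rng) for _ in range(5)]
        batch = prepare_batch(triples)
        params = init_params({"time": 40, "frequency": 4, "spatial": 1},
                             TrainConfig(seed=3))
        probs = forward(batch, params)
        assert probs.shape == (5, 2)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-8)

    def test_eval_deterministic(self, rng):
        triple = make_triple(rng)
        params = init_params({"time": 40, "frequency": 4, "spatial": 1},
                             TrainConfig(seed=3))
        p1 = forward(triple, params)
        p2 = forward(triple, params)
        assert np.array_equal(p1, p2)

    def test_zero_features_constant_output(self, rng):
        """All-zero node features die at the first ReLU, so every such
        input maps to the same bias-driven probability."""
        params = init_params({"time": 40, "frequency": 4, "spatial": 1},
                             TrainConfig(seed=3))
        outs = []
        for _ in range(3):
            graphs = []
            for domain, f in (("time", 40), ("frequency", 4), ("spatial", 1)):
                a = random_connected_adjacency(rng, 6)
                graphs.append(DomainGraph(
                    NodeFeatureMatrix(np.zeros((6, f)), domain),
                    AdjacencyMatrix(a, domain), {}))
            outs.append(forward(tuple(graphs), params))
        assert np.allclose(outs[0], outs[1], atol=1e-12)
        assert np.allclose(outs[0], outs[2], atol=1e-12)

    def test_permutation_equivariance(self, rng):
        """Consistently relabeling nodes leaves the pooled output
        unchanged."""
        params = init_params({"time": 40, "frequency": 4, "spatial": 1},
                             TrainConfig(seed=5))
        triple = make_triple(rng, s=7)
        perm = rng.permutation(7)
        permuted = tuple(
            DomainGraph(NodeFeatureMatrix(g.x.values[perm], g.domain),
                        AdjacencyMatrix(g.A.values[np.ix_(perm, perm)],
                                        g.domain), {})
            for g in triple)
        assert np.allclose(forward(triple, params),
                           forward(permuted, params), atol=1e-6)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Analytic gradients of the cross-entropy agree with central
        finite differences for every parameter tensor."""
        triples = [make_triple(rng, s=4, label=i % 2) for i in range(6)]
        batch = prepare_batch(triples)
        params = init_params({"time": 40, "frequency": 4, "spatial": 1},
                             TrainConfig(seed=11))
        params.dropout = 0.0          # keep-all masks make the loss smooth
        sw = np.full(6, 1 / 6)
        probs, cache = _forward(params, batch, True, np.random.default_rng(0))
        grads = _backward(params, batch, probs, cache, sw)

        def loss_with(ref, value):
            if ref[0] == "branch":
                old = params.branches[ref[1]][ref[2]][ref[3]]
                params.branches[ref[1]][ref[2]][ref[3]] = value
            else:
                old = getattr(params, ref[0])
                setattr(params, ref[0], value)
            p, _ = _forward(params, batch, True, np.random.default_rng(0))
            out = _loss(p, batch.labels, sw)
            if ref[0] == "branch":
                params.branches[ref[1]][ref[2]][ref[3]] = old
            else:
                setattr(params, ref[0], old)
            return out

        eps = 1e-6
        checks = [("branch", "time", 0, 0), ("branch", "frequency", 1, 0),
                  ("branch", "spatial", 0, 0), ("bn_gamma",), ("bn_beta",),
                  ("dense_w",), ("dense_b",)]
        for ref in checks:
            if ref[0] == "branch":
                w = params.branches[ref[1]][ref[2]][ref[3]]
                g = grads[f"branch_{ref[1]}"][ref[2]][ref[3]]
            else:
                w = getattr(params, ref[0])
                g = grads[ref[0]]
            idx = tuple(rng.integers(0, s) for s in w.shape)
            bump = np.zeros_like(w)
            bump[idx] = eps
            num = (loss_with(ref, w + bump) - loss_with(ref, w - bump)) / (2 * eps)
            assert abs(num - g[idx]) < 1e-5 * max(1.0, abs(num)), ref


class TestTraining:
    def test_loss_trace_deterministic(self, rng):
        triples = [make_triple(rng, label=i % 2) for i in range(10)]
        cfg = TrainConfig(epochs=20, seed=7)
        p1 = train_mgcn(triples, cfg)
        p2 = train_mgcn(triples, cfg)
        assert np.array_equal(p1.loss_trace, p2.loss_trace)
        assert params_digest(p1) == params_digest(p2)

    def test_separable_graphs_learned(self, rng):
        """Trials whose edges and features are uniformly shifted by class
        are fit to >= 95% training accuracy within 200 epochs."""
        triples, labels = [], []
        for i in range(40):
            label = i % 2
            scale = 1.5 if label else 0.5
            triples.append(make_triple(rng, s=8, label=label, scale=scale))
            labels.append(label)
        params = train_mgcn(triples, TrainConfig(epochs=200, seed=1))
        preds, _ = predict_trials(params, triples)
        assert (preds == np.array(labels)).mean() >= 0.95
        assert params.loss_trace[-1] < params.loss_trace[0]

    def test_single_class_rejected(self, rng):
        triples = [make_triple(rng, label=1) for _ in range(4)]
        with pytest.raises(ValueError, match="single class"):
            train_mgcn(triples, TrainConfig(epochs=5))

    def test_config_grid_enforced(self):
        with pytest.raises(ValueError, match="cheb_order"):
            TrainConfig(cheb_order=3)
        with pytest.raises(ValueError, match="dropout"):
            TrainConfig(dropout=0.4)

    def test_prediction_order_invariant(self, rng):
        triples = [make_triple(rng, label=i % 2) for i in range(8)]
        params = train_mgcn(triples, TrainConfig(epochs=30, seed=2))
        preds, _ = predict_trials(params, triples)
        rev_preds, _ = predict_trials(params, triples[::-1])
        assert np.array_equal(preds, rev_preds[::-1])
        assert set(np.unique(preds)) <= {0, 1}

    def test_params_roundtrip(self, rng, tmp_path):
        triples = [make_triple(rng, label=i % 2) for i in range(6)]
        params = train_mgcn(triples, TrainConfig(epochs=10, seed=4))
        path = tmp_path / "model.npz"
        params.save(path)
        loaded = MGCNParams.load(path)
        assert params_digest(loaded) == params_digest(params)
        assert np.array_equal(
            predict_trials(loaded, triples)[1],
            predict_trials(params, triples)[1])
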