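import numpy as np
import pytest

from peppinet.embedding import SequenceEmbedding
from peppinet.network import (
    ModelConfig,
    backward,
    bce_loss,
    bce_loss_grad,
    forward,
    forward_cached,
    gcn_layer,
    gin_layer,
    global_add_pool,
    init_parameters,
    load_checkpoint,
    normalized_adjacency,
    save_checkpoint,
)
from peppinet.pair_graph import PAIR_EDGE_INDEX, batch_graphs, build_pair_graph

from oracles import (
    bce_highprecision,
    dense_normalized_adjacency,
    reference_forward_pair_graph,
)


def _pair_batch(rng, dim, n=1, labels=False):
    graphs = [
        build_pair_graph(
            SequenceEmbedding(f"p{i}", rng.standard_normal(dim)),
            SequenceEmbedding(f"q{i}", rng.standard_normal(dim)),
            label=int(i % 2) if labels else None,
        )
        for i in range(n)
    ]
    return batch_graphs(graphs)


class TestNormalizedAdjacency:
    def test_pair_graph_is_half_everywhere(self):
        np.testing.assert_array_equal(
            normalized_adjacency(PAIR_EDGE_INDEX, 2), [[0.5, 0.5], [0.5, 0.5]]
        )

    def test_single_node_self_loop_only(self):
        np.testing.assert_array_equal(
            normalized_adjacency(np.zeros((2, 0), dtype=int), 1), [[1.0]]
        )

    def test_random_graph_matches_dense_oracle_and_symmetry(self):
        rng = np.random.default_rng(0)
        edges = rng.integers(0, 6, size=(2, 10))
        und = np.concatenate([edges, edges[::-1]], axis=1)  # undirected
        got = normalized_adjacency(und, 6)
        expected = dense_normalized_adjacency(und.tolist(), 6)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        np.testing.assert_allclose(got, got.T, atol=1e-12)

    def test_pair_graph_row_sums_are_one(self):
        assert normalized_adjacency(PAIR_EDGE_INDEX, 2).sum(axis=1) == pytest.approx([1.0, 1.0])


class TestGCNLayer:
    def test_bare_propagation_arithmetic(self):
        h = np.array([[2.0, 0.0], [0.0, 2.0]])
        out = gcn_layer(h, PAIR_EDGE_INDEX, W=np.eye(2), use_norm=False, use_relu=False)
        np.testing.assert_allclose(out, [[1.0, 1.0], [1.0, 1.0]], atol=1e-12)

    def test_pair_graph_rows_identical_for_any_weights(self):
        rng = np.random.default_rng(1)
        h = rng.standard_normal((2, 5))
        out = gcn_layer(h, PAIR_EDGE_INDEX, W=rng.standard_normal((5, 3)))
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_relu_zeroes_negative_preactivations(self):
        h = np.array([[1.0], [1.0]])
        out = gcn_layer(h, PAIR_EDGE_INDEX, W=np.array([[-3.0]]), use_norm=False)
        np.testing.assert_array_equal(out, np.zeros((2, 1)))


class TestGINLayer:
    def test_single_neighbor_sum(self):
        h = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = gin_layer(h, PAIR_EDGE_INDEX, mlp=lambda x: x, epsilon=0.0)
        np.testing.assert_allclose(out[0], [4.0, 6.0], atol=1e-12)

    def test_isolated_node_unchanged(self):
        h = np.array([[1.0, -2.0], [0.5, 0.5], [9.0, 9.0]])
        edges = np.array([[1], [2]])  # node 0 has no neighbors
        out = gin_layer(h, edges, mlp=lambda x: x, epsilon=0.0)
        np.testing.assert_array_equal(out[0], h[0])

    def test_random_graph_matches_neighbor_sum_loop(self):
        rng = np.random.default_rng(2)
        n = 8
        edges = rng.integers(0, n, size=(2, 20))
        edges = edges[:, edges[0] != edges[1]]
        h = rng.standard_normal((n, 4))
        eps = 0.3
        out = gin_layer(h, edges, mlp=lambda x: x, epsilon=eps)
        seen = set(map(tuple, edges.T))
        for v in range(n):
            acc = (1 + eps) * h[v].copy()
            for u in range(n):
                if (u, v) in seen:
                    acc += h[u]
            np.testing.assert_allclose(out[v], acc, atol=1e-12)


def test_global_add_pool_sums():
    h = np.array([[1.0, 2.0], [3.0, 4.0]])
    np.testing.assert_array_equal(global_add_pool(h, [0, 0]), [[4.0, 6.0]])
    np.testing.assert_array_equal(global_add_pool(h[:1], [0]), [[1.0, 2.0]])


class TestForward:
    def test_matches_dense_reference_on_random_pair_graphs(self):
        rng = np.random.default_rng(3)
        config = ModelConfig(input_dim=10, gcn_dims=(7, 7), gin_dims=(7, 4))
        params = init_parameters(config, seed=11)
        for i in range(20):
            batch = _pair_batch(np.random.default_rng(100 + i), 10)
            logit = forward_cached(batch, params, config)[0][0]
            ref = reference_forward_pair_graph(batch.node_features, params, config)
            assert logit == pytest.approx(ref, abs=1e-6)

    def test_probability_range_and_determinism(self):
        rng = np.random.default_rng(4)
        config = ModelConfig(input_dim=6, gcn_dims=(5, 5), gin_dims=(5, 3))
        params = init_parameters(config, seed=0)
        batch = _pair_batch(rng, 6, n=8, labels=True)
        preds1 = forward(batch, params, config)
        preds2 = forward(batch, params, config)
        assert all(0.0 <= p.probability <= 1.0 for p in preds1)
        assert [p.logit for p in preds1] == [p.logit for p in preds2]

    def test_pair_symmetry_under_node_swap(self):
        """Self-loops make layer 1 depend only on the node sum, so swapping
        the peptide and protein rows must not change the probability."""
        config = ModelConfig(input_dim=8, gcn_dims=(6, 6), gin_dims=(6, 4))
        for draw in range(20):
            rng = np.random.default_rng(draw)
            params = init_parameters(config, seed=draw)
            x = rng.standard_normal((2, 8))
            from peppinet.pair_graph import GraphBatch

            b_fwd = GraphBatch(x, PAIR_EDGE_INDEX, np.array([0, 0]),
                               np.array([-1]), ("g",))
            b_swp = GraphBatch(x[::-1].copy(), PAIR_EDGE_INDEX, np.array([0, 0]),
                               np.array([-1]), ("g",))
            za = forward_cached(b_fwd, params, config)[0][0]
            zb = forward_cached(b_swp, params, config)[0][0]
            assert za == pytest.approx(zb, abs=1e-6)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(5)
        config = ModelConfig(input_dim=8, gcn_dims=(5, 5), gin_dims=(5, 4))
        params = init_parameters(config, seed=3)
        batch = _pair_batch(rng, 8, n=6, labels=True)
        labels = batch.labels.astype(float)
        logits, caches = forward_cached(batch, params, config)
        grads = backward(bce_loss_grad(logits, labels), batch, params, config, caches)
        eps = 1e-6
        for k in params:
            g = np.asarray(grads[k]).reshape(params[k].shape)
            idx = tuple(rng.integers(s) for s in params[k].shape)
            orig = params[k][idx]
            params[k][idx] = orig + eps
            lp = bce_loss(forward_cached(batch, params, config)[0], labels)
            params[k][idx] = orig - eps
            lm = bce_loss(forward_cached(batch, params, config)[0], labels)
            params[k][idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(fd, rel=1e-3, abs=1e-8), k


class TestBCELoss:
    def test_zero_logits_give_ln2(self):
        assert bce_loss(np.zeros(2), np.array([1.0, 0.0])) == pytest.approx(
            np.log(2.0), abs=1e-12
        )

    def test_saturation_is_finite(self):
        assert bce_loss(np.array([50.0]), np.array([1.0])) == pytest.approx(0.0, abs=1e-12)
        assert np.isfinite(bce_loss(np.array([-50.0]), np.array([1.0])))

    def test_matches_high_precision_oracle(self):
        rng = np.random.default_rng(6)
        logits = rng.standard_normal(100) * 5
        labels = rng.integers(0, 2, size=100).astype(float)
        assert bce_loss(logits, labels) == pytest.approx(
            bce_highprecision(logits, labels), abs=1e-10
        )

    def test_nonnegative_and_input_validation(self):
        rng = np.random.default_rng(7)
        assert bce_loss(rng.standard_normal(20), rng.integers(0, 2, 20).astype(float)) >= 0
        with pytest.raises(ValueError):
            bce_loss(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            bce_loss(np.zeros(2), np.array([0.5, 1.0]))


def test_checkpoint_round_trip(tmp_path):
    from peppinet.embedding import NormalizationStats

    config = ModelConfig(input_dim=9, gcn_dims=(4, 4), gin_dims=(4, 3))
    params = init_parameters(config, seed=8)
    stats = NormalizationStats(
        mean=np.arange(9.0), std=np.ones(9), fit_fingerprint="abc"
    )
    path = tmp_path / "model.ckpt"
    save_checkpoint(path, config, params, stats, threshold=0.42, seed=77)
    cfg2, params2, stats2, thr, seed = load_checkpoint(path)
    assert cfg2 == config and thr == 0.42 and seed == 77
    assert set(params2) == set(params)
    for k in params:
        np.testing.assert_array_equal(params2[k], params[k])
    np.testing.assert_array_equal(stats2.mean, stats.mean)
    assert stats2.fit_fingerprint == "abc"
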