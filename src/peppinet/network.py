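"""Hybrid GCN/GIN classifier over pair graphs, implemented in NumPy.

Architecture (per pair graph):

    x -> GCNConv(D -> 64) -> GCNConv(64 -> 64)
      -> GINConv(64 -> 64) -> GINConv(64 -> 32)
      -> global add pooling -> dropout -> linear -> logit -> sigmoid

Each graph-convolution layer propagates with the symmetrically normalized
adjacency with self-loops,

    H' = ReLU(Norm(D^-1/2 (A + I) D^-1/2 H W)),

followed by 20% dropout during training.  Each graph-isomorphism layer
computes mlp((1 + eps) * h_v + sum_{u in N(v)} h_u) with the neighborhood
taken from the stored (self-loop-free) edge list and a two-layer MLP
(linear -> ReLU -> linear).  The loss is binary cross-entropy evaluated in
logit space for numerical stability.

Normalization: the default mode standardizes each node's feature vector
across channels (with learnable affine).  On the 2-node pair graph with
self-loops both rows are identical after propagation, so classic per-graph
cross-node instance normalization would zero the features; that mode is
retained as an epsilon-guarded option (``per_graph_channel``) but is not
the default.

Gradients for every operation are written out explicitly so the model can
be trained with Adam without an autodiff framework.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .embedding import NormalizationStats
from .pair_graph import GraphBatch

NORM_EPS = 1e-5


@dataclass(frozen=True)
class ModelConfig:
    input_dim: int = 1024
    gcn_dims: tuple[int, int] = (64, 64)
    gin_dims: tuple[int, int] = (64, 32)
    dropout_rate: float = 0.2
    add_self_loops: bool = True
    norm_mode: str = "per_node_feature"  # or "per_graph_channel"
    gin_epsilon: float = 0.0

    def __post_init__(self):
        if any(w < 1 for w in (self.input_dim, *self.gcn_dims, *self.gin_dims)):
            raise ValueError("all layer widths must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.norm_mode not in ("per_node_feature", "per_graph_channel"):
            raise ValueError(f"unknown norm_mode {self.norm_mode!r}")


@dataclass(frozen=True)
class Prediction:
    pair_id: str
    logit: float
    probability: float


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# parameters


class ModelParameters(dict):
    """Named weight arrays; a plain dict with copy/arith helpers."""

    def copy(self) -> "ModelParameters":
        return ModelParameters({k: v.copy() for k, v in self.items()})


def init_parameters(config: ModelConfig, seed: int = 1234) -> ModelParameters:
    """Uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    rng = np.random.default_rng(seed)
    p = ModelParameters()

    def lin(name, fan_in, fan_out):
        bound = 1.0 / np.sqrt(fan_in)
        p[f"{name}_W"] = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        p[f"{name}_b"] = rng.uniform(-bound, bound, size=fan_out)

    d_in = config.input_dim
    for i, width in enumerate(config.gcn_dims):
        lin(f"gcn{i}", d_in, width)
        p[f"gcn{i}_gamma"] = np.ones(width)
        p[f"gcn{i}_beta"] = np.zeros(width)
        d_in = width
    for i, width in enumerate(config.gin_dims):
        # two-layer MLP, hidden width = output width
        lin(f"gin{i}_l1", d_in, width)
        lin(f"gin{i}_l2", width, width)
        d_in = width
    lin("head", d_in, 1)
    return p


# ---------------------------------------------------------------------------
# graph operators


def normalized_adjacency(
    edge_index: np.ndarray, n_nodes: int, add_self_loops: bool = True
) -> np.ndarray:
    """Dense symmetrically normalized adjacency D^-1/2 (A + I) D^-1/2.

    Duplicate directed edges collapse to a single adjacency entry; every
    node keeps degree >= 1 through its self-loop, so no isolated-node
    special case is needed.
    """
    edge_index = np.asarray(edge_index, dtype=np.int64)
    a = np.zeros((n_nodes, n_nodes))
    if edge_index.size:
        if edge_index.min() < 0 or edge_index.max() >= n_nodes:
            raise ValueError("edge index out of range")
        a[edge_index[0], edge_index[1]] = 1.0
    if add_self_loops:
        np.fill_diagonal(a, 1.0)
    deg = a.sum(axis=1)
    # divide by sqrt(d_i * d_j) in one step: exact for the 2-node pair graph
    denom = np.sqrt(np.outer(deg, deg))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, a / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def _adjacency_plain(edge_index: np.ndarray, n_nodes: int) -> np.ndarray:
    """Unnormalized, self-loop-free binary adjacency (GIN neighborhood)."""
    a = np.zeros((n_nodes, n_nodes))
    if edge_index.size:
        a[edge_index[0], edge_index[1]] = 1.0
    np.fill_diagonal(a, 0.0)
    return a


# --- normalization forward/backward


def _norm_forward(z, membership, gamma, beta, mode):
    if mode == "per_node_feature":
        mu = z.mean(axis=1, keepdims=True)
        var = z.var(axis=1, keepdims=True)
        std = np.sqrt(var + NORM_EPS)
        xhat = (z - mu) / std
    else:  # per_graph_channel: normalize each channel across a graph's nodes
        n_graphs = membership.max() + 1
        counts = np.bincount(membership, minlength=n_graphs)[:, None]
        mu_g = np.zeros((n_graphs, z.shape[1]))
        np.add.at(mu_g, membership, z)
        mu_g /= counts
        cen = z - mu_g[membership]
        var_g = np.zeros((n_graphs, z.shape[1]))
        np.add.at(var_g, membership, cen ** 2)
        var_g /= counts
        std = np.sqrt(var_g + NORM_EPS)[membership]
        xhat = cen / std
    out = gamma * xhat + beta
    return out, (xhat, std, gamma, membership, mode)


def _norm_backward(dout, cache):
    xhat, std, gamma, membership, mode = cache
    dgamma = (dout * xhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    dxhat = dout * gamma
    if mode == "per_node_feature":
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
        dz = (dxhat - m1 - xhat * m2) / std
    else:
        n_graphs = membership.max() + 1
        counts = np.bincount(membership, minlength=n_graphs)[:, None]
        s1 = np.zeros((n_graphs, dxhat.shape[1]))
        np.add.at(s1, membership, dxhat)
        s2 = np.zeros((n_graphs, dxhat.shape[1]))
        np.add.at(s2, membership, dxhat * xhat)
        dz = (dxhat - (s1 / counts)[membership] - xhat * (s2 / counts)[membership]) / std
    return dz, dgamma, dbeta


def _dropout_forward(x, rate, training, rng):
    if not training or rate == 0.0:
        return x, None
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * mask, mask


# ---------------------------------------------------------------------------
# public single-layer operations (inference form)


def gcn_layer(
    h: np.ndarray,
    edge_index: np.ndarray,
    W: np.ndarray,
    b: np.ndarray | None = None,
    gamma: np.ndarray | None = None,
    beta: np.ndarray | None = None,
    membership: np.ndarray | None = None,
    config: ModelConfig | None = None,
    training: bool = False,
    rng: np.random.Generator | None = None,
    use_norm: bool = True,
    use_relu: bool = True,
):
    """One graph-convolution layer: propagate, map, normalize, ReLU, dropout.

    With ``use_norm=False``/``use_relu=False`` the raw propagated linear
    map is returned, which is convenient for hand-checkable arithmetic.
    """
    config = config or ModelConfig(input_dim=h.shape[1])
    h = np.asarray(h, dtype=np.float64)
    p = normalized_adjacency(edge_index, h.shape[0], config.add_self_loops)
    z = p @ h @ W
    if b is not None:
        z = z + b
    if use_norm:
        if membership is None:
            membership = np.zeros(h.shape[0], dtype=np.int64)
        gamma = np.ones(z.shape[1]) if gamma is None else gamma
        beta = np.zeros(z.shape[1]) if beta is None else beta
        z, _ = _norm_forward(z, membership, gamma, beta, config.norm_mode)
    if use_relu:
        z = np.maximum(z, 0.0)
    if training:
        z, _ = _dropout_forward(z, config.dropout_rate, True, rng or np.random.default_rng())
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite output from gcn_layer")
    return z


def gin_layer(
    h: np.ndarray,
    edge_index: np.ndarray,
    mlp,
    epsilon: float = 0.0,
) -> np.ndarray:
    """One graph-isomorphism layer: mlp((1+eps) h_v + sum of neighbors).

    ``mlp`` is any callable on the aggregated node matrix; the stored edge
    list (no self-loops) defines the neighborhood.
    """
    h = np.asarray(h, dtype=np.float64)
    a = _adjacency_plain(np.asarray(edge_index, dtype=np.int64), h.shape[0])
    agg = (1.0 + epsilon) * h + a.T @ h  # sum over in-neighbors u: u -> v
    return mlp(agg)


def global_add_pool(h: np.ndarray, membership: np.ndarray) -> np.ndarray:
    """Sum node rows within each graph."""
    membership = np.asarray(membership, dtype=np.int64)
    n_graphs = int(membership.max()) + 1
    out = np.zeros((n_graphs, h.shape[1]))
    np.add.at(out, membership, h)
    return out


# ---------------------------------------------------------------------------
# full forward / backward


def _mlp2_forward(x, W1, b1, W2, b2):
    z1 = x @ W1 + b1
    a1 = np.maximum(z1, 0.0)
    out = a1 @ W2 + b2
    return out, (x, z1, a1, W1, W2)


def _mlp2_backward(dout, cache):
    x, z1, a1, W1, W2 = cache
    dW2 = a1.T @ dout
    db2 = dout.sum(axis=0)
    da1 = dout @ W2.T
    dz1 = da1 * (z1 > 0)
    dW1 = x.T @ dz1
    db1 = dz1.sum(axis=0)
    dx = dz1 @ W1.T
    return dx, dW1, db1, dW2, db2


def forward_cached(
    batch: GraphBatch,
    params: ModelParameters,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
):
    """Full forward pass returning logits and the caches needed for backprop."""
    if training and rng is None:
        rng = np.random.default_rng()
    h = batch.node_features
    n = h.shape[0]
    p_norm = normalized_adjacency(batch.edge_index, n, config.add_self_loops)
    a_plain = _adjacency_plain(batch.edge_index, n)
    caches: dict = {"p_norm": p_norm, "a_plain": a_plain}

    for i in range(len(config.gcn_dims)):
        m = p_norm @ h
        z = m @ params[f"gcn{i}_W"] + params[f"gcn{i}_b"]
        zn, norm_cache = _norm_forward(
            z, batch.membership, params[f"gcn{i}_gamma"], params[f"gcn{i}_beta"], config.norm_mode
        )
        act = np.maximum(zn, 0.0)
        out, mask = _dropout_forward(act, config.dropout_rate, training, rng)
        caches[f"gcn{i}"] = (h, m, zn, norm_cache, mask)
        h = out

    for i in range(len(config.gin_dims)):
        agg = (1.0 + config.gin_epsilon) * h + a_plain.T @ h
        out, mlp_cache = _mlp2_forward(
            agg,
            params[f"gin{i}_l1_W"], params[f"gin{i}_l1_b"],
            params[f"gin{i}_l2_W"], params[f"gin{i}_l2_b"],
        )
        caches[f"gin{i}"] = mlp_cache
        h = out

    pooled = global_add_pool(h, batch.membership)
    pooled_dropped, pool_mask = _dropout_forward(pooled, config.dropout_rate, training, rng)
    logits = (pooled_dropped @ params["head_W"] + params["head_b"]).ravel()
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite logits in forward pass")
    caches["pool"] = (pooled_dropped, pool_mask)
    return logits, caches


def backward(
    dlogits: np.ndarray,
    batch: GraphBatch,
    params: ModelParameters,
    config: ModelConfig,
    caches: dict,
) -> dict[str, np.ndarray]:
    """Gradients of the scalar loss w.r.t. every parameter array."""
    grads: dict[str, np.ndarray] = {}
    pooled_dropped, pool_mask = caches["pool"]
    dl = dlogits[:, None]
    grads["head_W"] = pooled_dropped.T @ dl
    grads["head_b"] = dl.sum(axis=0)
    dpooled = dl @ params["head_W"].T
    if pool_mask is not None:
        dpooled = dpooled * pool_mask
    # un-pool: gradient broadcasts back to each node of the graph
    dh = dpooled[batch.membership]

    a_plain = caches["a_plain"]
    for i in reversed(range(len(config.gin_dims))):
        dagg, dW1, db1, dW2, db2 = _mlp2_backward(dh, caches[f"gin{i}"])
        grads[f"gin{i}_l1_W"] = dW1
        grads[f"gin{i}_l1_b"] = db1
        grads[f"gin{i}_l2_W"] = dW2
        grads[f"gin{i}_l2_b"] = db2
        dh = (1.0 + config.gin_epsilon) * dagg + a_plain @ dagg

    p_norm = caches["p_norm"]
    for i in reversed(range(len(config.gcn_dims))):
        h_in, m, zn, norm_cache, mask = caches[f"gcn{i}"]
        if mask is not None:
            dh = dh * mask
        dzn = dh * (zn > 0)
        dz, dgamma, dbeta = _norm_backward(dzn, norm_cache)
        grads[f"gcn{i}_gamma"] = dgamma
        grads[f"gcn{i}_beta"] = dbeta
        grads[f"gcn{i}_W"] = m.T @ dz
        grads[f"gcn{i}_b"] = dz.sum(axis=0)
        dm = dz @ params[f"gcn{i}_W"].T
        dh = p_norm.T @ dm
    return grads


def forward(
    batch: GraphBatch,
    params: ModelParameters,
    config: ModelConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> list[Prediction]:
    """Predict each graph in the batch; deterministic in evaluation mode."""
    logits, _ = forward_cached(batch, params, config, training=training, rng=rng)
    probs = sigmoid(logits)
    return [
        Prediction(pair_id=pid, logit=float(z), probability=float(p))
        for pid, z, p in zip(batch.pair_ids, logits, probs)
    ]


def bce_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy, computed in logit space.

    loss_i = max(z, 0) - z*y + log(1 + exp(-|z|)), the numerically stable
    form of -[y log sigmoid(z) + (1-y) log(1 - sigmoid(z))].
    """
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if z.size == 0:
        raise ValueError("bce_loss on empty input")
    if z.shape != y.shape:
        raise ValueError("logits and labels must have equal length")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be 0/1")
    per = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(per.mean())


def bce_loss_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d logits = (sigmoid(z) - y) / N."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    return (sigmoid(z) - y) / z.size


# ---------------------------------------------------------------------------
# checkpoint I/O


def save_checkpoint(
    path,
    config: ModelConfig,
    params: ModelParameters,
    stats: NormalizationStats,
    threshold: float,
    seed: int,
) -> None:
    """Serialize config + weights + normalization stats + threshold + seed."""
    meta = {
        "config": {**asdict(config),
                   "gcn_dims": list(config.gcn_dims),
                   "gin_dims": list(config.gin_dims)},
        "threshold": float(threshold),
        "seed": int(seed),
        "stats_epsilon": stats.epsilon,
        "stats_fingerprint": stats.fit_fingerprint,
    }
    arrays = {f"param_{k}": v for k, v in params.items()}
    arrays["stats_mean"] = stats.mean
    arrays["stats_std"] = stats.std
    with open(path, "wb") as fh:  # explicit handle: no implicit .npz suffix
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Inverse of save_checkpoint; round-trips bit-exactly."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["gcn_dims"] = tuple(cfg_d["gcn_dims"])
        cfg_d["gin_dims"] = tuple(cfg_d["gin_dims"])
        config = ModelConfig(**cfg_d)
        params = ModelParameters(
            {k[len("param_"):]: data[k].copy() for k in data.files if k.startswith("param_")}
        )
        stats = NormalizationStats(
            mean=data["stats_mean"].copy(),
            std=data["stats_std"].copy(),
            epsilon=meta["stats_epsilon"],
            fit_fingerprint=meta["stats_fingerprint"],
        )
    return config, params, stats, meta["threshold"], meta["seed"]
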