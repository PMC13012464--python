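"""Independent brute-force reference implementations used as test oracles.

Everything here is written with explicit loops and dense matrices, sharing
no code with the package's implementation paths.
"""

import math

import numpy as np


def dense_normalized_adjacency(edges, n):
    """D^-1/2 (A + I) D^-1/2 via explicit dense construction."""
    a = [[0.0] * n for _ in range(n)]
    for s, t in zip(edges[0], edges[1]):
        a[s][t] = 1.0
    for i in range(n):
        a[i][i] = 1.0
    deg = [sum(row) for row in a]
    out = [[a[i][j] / math.sqrt(deg[i] * deg[j]) for j in range(n)] for i in range(n)]
    return np.array(out)


def _layernorm_rows(z, gamma, beta, eps=1e-5):
    out = np.empty_like(z)
    for i in range(z.shape[0]):
        row = z[i]
        mu = row.mean()
        var = ((row - mu) ** 2).mean()
        out[i] = gamma * (row - mu) / math.sqrt(var + eps) + beta
    return out


def reference_forward_pair_graph(x, params, config):
    """Evaluation-mode forward pass for a single 2-node pair graph.

    Dense-matrix re-implementation of the full stack: two GCN layers with
    self-loops, layer normalization and ReLU; two GIN layers with the
    stored bidirectional edges; add pooling; linear head.
    """
    edges = ([0, 1], [1, 0])
    p = dense_normalized_adjacency(edges, 2)
    h = np.array(x, dtype=float)
    for i in range(len(config.gcn_dims)):
        z = p @ h @ params[f"gcn{i}_W"] + params[f"gcn{i}_b"]
        zn = _layernorm_rows(z, params[f"gcn{i}_gamma"], params[f"gcn{i}_beta"])
        h = np.maximum(zn, 0.0)
    # plain adjacency for GIN (no self-loops)
    a = np.array([[0.0, 1.0], [1.0, 0.0]])
    for i in range(len(config.gin_dims)):
        agg = (1.0 + config.gin_epsilon) * h + a @ h
        z1 = np.maximum(agg @ params[f"gin{i}_l1_W"] + params[f"gin{i}_l1_b"], 0.0)
        h = z1 @ params[f"gin{i}_l2_W"] + params[f"gin{i}_l2_b"]
    pooled = h.sum(axis=0)
    return float(pooled @ params["head_W"][:, 0] + params["head_b"][0])


def auc_pairwise(scores, labels):
    """O(n^2) rank statistic: (concordant + 0.5 * ties) / (n_pos * n_neg)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_sweep(scores, labels):
    """Naive threshold-sweep integration of precision over recall.

    Thresholds at every distinct score (descending), ties as a block;
    AUPR = sum over steps of (R_i - R_{i-1}) * P_i.
    """
    scores = list(scores)
    labels = list(labels)
    n_pos = sum(labels)
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = [s >= t for s in scores]
        tp = sum(1 for p, y in zip(pred, labels) if p and y == 1)
        fp = sum(1 for p, y in zip(pred, labels) if p and y == 0)
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def f1_at(scores, labels, threshold):
    tp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 1)
    fp = sum(1 for s, y in zip(scores, labels) if s >= threshold and y == 0)
    fn = sum(1 for s, y in zip(scores, labels) if s < threshold and y == 1)
    return 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)


def best_f1_exhaustive(scores, labels):
    """Max F1 over every candidate threshold (all scores plus 0 and 1)."""
    candidates = set(scores) | {0.0, 1.0}
    return max(f1_at(scores, labels, t) for t in candidates)


def bce_highprecision(logits, labels):
    """Direct high-precision evaluation of the cross-entropy definition."""
    from mpmath import mp, mpf, log, exp

    mp.dps = 50
    total = mpf(0)
    for z, y in zip(logits, labels):
        p = 1 / (1 + exp(-mpf(float(z))))
        total += -(mpf(int(y)) * log(p) + (1 - mpf(int(y))) * log(1 - p))
    return float(total / len(logits))


def paired_t_p_value(a, b):
    """Two-sided p from the t CDF, statistic computed by hand."""
    from scipy.stats import t as tdist

    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
    stat = mean / (sd / math.sqrt(n))
    return 2 * tdist.sf(abs(stat), n - 1)
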