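"""Seeded training: Adam, early stopping, cross-validation, threshold choice.

The protocol: Adam (learning rate 1e-3, weight decay 5e-4), binary
cross-entropy in logit space, early stopping on validation AUC with
patience 10 and best-parameter restore, and a dynamic decision threshold
chosen to maximize F1 on the validation scores.  A fixed seed (default
1234) makes runs bit-reproducible.  Normalization statistics are fit on
each fold's training entities only and frozen into the trained model, so
no test information leaks into standardization, early stopping or
threshold selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .embedding import SequenceEmbedding, NormalizationStats, fit_zscore, apply_zscore
from .pair_graph import PairGraph, build_pair_graph, batch_graphs
from .network import (
    ModelConfig,
    ModelParameters,
    Prediction,
    init_parameters,
    forward_cached,
    bce_loss,
    bce_loss_grad,
    backward,
    sigmoid,
)
from .sequence_io import PairExample


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 5e-4
    seed: int = 1234
    patience: int = 10
    max_epochs: int = 200
    batch_size: int = 64
    validation_fraction: float = 0.1

    def __post_init__(self):
        if min(self.learning_rate, self.weight_decay, self.patience,
               self.max_epochs, self.batch_size) <= 0:
            raise ValueError("all training hyperparameters must be positive")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        a, b, c = set(self.train_ids), set(self.val_ids), set(self.test_ids)
        if a & b or a & c or b & c:
            raise ValueError("fold id sets must be pairwise disjoint")


@dataclass
class TrainedModel:
    model_config: ModelConfig
    params: ModelParameters
    stats: NormalizationStats
    threshold: float
    history: list[dict]
    best_epoch: int
    seed: int


def pair_key(p: PairExample) -> str:
    return f"{p.peptide_id}|{p.protein_id}"


def make_cv_folds(
    pairs: Sequence[PairExample],
    k: int = 5,
    seed: int = 1234,
    validation_fraction: float = 0.1,
) -> list[FoldSplit]:
    """Stratified k-fold splits with a stratified validation carve-out.

    Each example lands in exactly one test fold; within each fold,
    ``validation_fraction`` of the training portion is held out for early
    stopping and threshold selection.
    """
    keys = np.array([pair_key(p) for p in pairs])
    labels = np.array([p.label for p in pairs])
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate pair keys in dataset")
    for cls in (0, 1):
        if (labels == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (train_idx, test_idx) in enumerate(skf.split(keys, labels)):
        try:
            tr, va = train_test_split(
                train_idx,
                test_size=validation_fraction,
                stratify=labels[train_idx],
                random_state=seed + i,
            )
        except ValueError:  # carve-out too small to stratify: plain shuffle split
            tr, va = train_test_split(
                train_idx, test_size=validation_fraction, random_state=seed + i
            )
        folds.append(
            FoldSplit(
                fold_index=i,
                train_ids=tuple(keys[np.sort(tr)]),
                val_ids=tuple(keys[np.sort(va)]),
                test_ids=tuple(keys[np.sort(test_idx)]),
            )
        )
    return folds


def select_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Smallest threshold (midpoints of distinct sorted scores plus {0,1})
    maximizing F1 with the inclusive rule: predict positive iff score >= t."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("threshold selection requires at least one positive label")
    distinct = np.unique(scores)
    candidates = np.concatenate([[0.0], (distinct[:-1] + distinct[1:]) / 2.0, [1.0]])
    best_t, best_f1 = None, -1.0
    for t in np.sort(candidates):
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
        if f1 > best_f1 + 1e-12:
            best_f1, best_t = f1, float(t)
    return best_t


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # local rank-based AUC (keeps training free of the evaluation module)
    from scipy.stats import rankdata

    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


class AdamOptimizer:
    """Adam with L2-style weight decay added to the gradient."""

    def __init__(self, params: ModelParameters, lr: float, weight_decay: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: ModelParameters, grads: Mapping[str, np.ndarray]) -> None:
        self.t += 1
        for k in params:
            g = np.asarray(grads[k]).reshape(params[k].shape) + self.wd * params[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def standardize_and_build(
    pairs: Sequence[PairExample],
    embeddings: Mapping[str, SequenceEmbedding],
    stats: NormalizationStats,
) -> dict[str, PairGraph]:
    """Apply frozen normalization stats and assemble pair graphs."""
    graphs = {}
    for p in pairs:
        pep = apply_zscore(embeddings[p.peptide_id], stats)
        prot = apply_zscore(embeddings[p.protein_id], stats)
        graphs[pair_key(p)] = build_pair_graph(pep, prot, label=p.label)
    return graphs


def fit_fold_stats(
    train_pairs: Sequence[PairExample],
    embeddings: Mapping[str, SequenceEmbedding],
) -> NormalizationStats:
    """Z-score statistics from the entities of the training pairs only.

    Peptides and proteins share one statistic set because they share one
    node-feature space in the graph.
    """
    train_entities = sorted(
        {p.peptide_id for p in train_pairs} | {p.protein_id for p in train_pairs}
    )
    return fit_zscore([embeddings[e] for e in train_entities])


def _scores_for(ids, graphs, params, model_config):
    batch = batch_graphs([graphs[i] for i in ids])
    logits, _ = forward_cached(batch, params, model_config, training=False)
    return sigmoid(logits), batch.labels.astype(np.float64)


def train_model(
    fold: FoldSplit,
    pairs: Sequence[PairExample],
    embeddings: Mapping[str, SequenceEmbedding],
    config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
) -> TrainedModel:
    """Train on one fold with Adam, early stopping and threshold selection.

    Normalization statistics come from the fold's training pairs only; the
    validation carve-out drives early stopping (monitored metric:
    validation AUC, threshold-free) and the final F1-maximizing threshold.
    """
    config = config or TrainConfig()
    by_key = {pair_key(p): p for p in pairs}
    for ids in (fold.train_ids, fold.val_ids, fold.test_ids):
        for i in ids:
            if i not in by_key:
                raise KeyError(f"fold references unknown pair {i!r}")

    train_pairs = [by_key[i] for i in fold.train_ids]
    stats = fit_fold_stats(train_pairs, embeddings)
    used_pairs = [by_key[i] for i in fold.train_ids + fold.val_ids + fold.test_ids]
    graphs = standardize_and_build(used_pairs, embeddings, stats)

    dim = next(iter(graphs.values())).dim
    if model_config is None:
        model_config = ModelConfig(input_dim=dim)
    elif model_config.input_dim != dim:
        raise ValueError(
            f"model input_dim {model_config.input_dim} != embedding dim {dim}"
        )

    rng = np.random.default_rng(config.seed)
    params = init_parameters(model_config, seed=config.seed)
    opt = AdamOptimizer(params, config.learning_rate, config.weight_decay)

    train_ids = list(fold.train_ids)
    history: list[dict] = []
    best_auc, best_epoch, best_params = -np.inf, -1, params.copy()
    since_best = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_ids))
        losses = []
        for start in range(0, len(order), config.batch_size):
            chunk = [train_ids[j] for j in order[start : start + config.batch_size]]
            batch = batch_graphs([graphs[i] for i in chunk])
            labels = batch.labels.astype(np.float64)
            logits, caches = forward_cached(
                batch, params, model_config, training=True, rng=rng
            )
            loss = bce_loss(logits, labels)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            losses.append(loss)
            grads = backward(
                bce_loss_grad(logits, labels), batch, params, model_config, caches
            )
            opt.step(params, grads)

        val_scores, val_labels = _scores_for(fold.val_ids, graphs, params, model_config)
        val_auc = _rank_auc(val_scores, val_labels)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_auc": float(val_auc)})
        if val_auc > best_auc:
            best_auc, best_epoch, best_params = val_auc, epoch, params.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    params = best_params
    val_scores, val_labels = _scores_for(fold.val_ids, graphs, params, model_config)
    threshold = select_threshold(val_scores, val_labels)
    return TrainedModel(
        model_config=model_config,
        params=params,
        stats=stats,
        threshold=threshold,
        history=history,
        best_epoch=best_epoch,
        seed=config.seed,
    )


def predict_pairs(
    model: TrainedModel,
    pairs: Sequence[PairExample],
    embeddings: Mapping[str, SequenceEmbedding],
) -> list[Prediction]:
    """Evaluation-mode predictions using the model's frozen statistics."""
    graphs = standardize_and_build(pairs, embeddings, model.stats)
    batch = batch_graphs([graphs[pair_key(p)] for p in pairs])
    logits, _ = forward_cached(batch, model.params, model.model_config, training=False)
    probs = sigmoid(logits)
    return [
        Prediction(pair_id=pid, logit=float(z), probability=float(pr))
        for pid, z, pr in zip(batch.pair_ids, logits, probs)
    ]
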