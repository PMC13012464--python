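"""Binary-classification metrics (ACC, F1, AUC, AUPR) and fold-level t-tests.

Conventions: the decision rule is inclusive (predict positive iff
probability >= threshold); F1 = 0 when TP = 0 but errors exist; AUC is the
rank statistic (concordant pairs + half of ties over n_pos * n_neg); AUPR
is the step-wise integral of precision over recall with tied scores
handled as a block; cross-validated methods are compared with a paired
two-sided t-test on the per-fold accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import roc_auc_score, average_precision_score


@dataclass(frozen=True)
class MetricsReport:
    acc: float
    f1: float
    auc: float
    aupr: float
    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int

    def as_dict(self) -> dict:
        return {
            "ACC": self.acc, "F1": self.f1, "AUC": self.auc, "AUPR": self.aupr,
            "threshold": self.threshold,
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
        }


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    p_value: float
    differences: tuple[float, ...]
    degenerate: bool = False


def confusion_counts(probs, labels, threshold: float) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) under the inclusive rule prob >= threshold."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    pred = probs >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, tn, fp, fn


def accuracy_f1(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float]:
    """ACC = (TP+TN)/total; F1 = 2PR/(P+R) with P = TP/(TP+FP), R = TP/(TP+FN)."""
    total = tp + tn + fp + fn
    if total <= 0:
        raise ValueError("no examples to evaluate")
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("negative confusion counts")
    acc = (tp + tn) / total
    if tp == 0:
        f1 = 1.0 if fp == 0 and fn == 0 else 0.0
    else:
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        f1 = 2 * precision * recall / (precision + recall)
    return acc, f1


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (equals the Mann-Whitney rank statistic)."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise integration)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("aupr requires at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=np.float64)))


def paired_t_test(acc_a, acc_b) -> TTestResult:
    """Paired two-sided t-test on per-fold metric differences.

    Degenerate conventions: zero-variance differences give p = 1 when the
    mean difference is 0 and p = 0 (flagged) otherwise.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of at least 2 folds")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return TTestResult(0.0, 1.0, tuple(diff), degenerate=True)
        return TTestResult(np.sign(diff.mean()) * np.inf, 0.0, tuple(diff), degenerate=True)
    res = sstats.ttest_rel(a, b)
    return TTestResult(float(res.statistic), float(res.pvalue), tuple(diff))


def evaluate_predictions(probs, labels, threshold: float = 0.5) -> MetricsReport:
    """Full metrics report for one evaluation run at a fixed threshold."""
    tp, tn, fp, fn = confusion_counts(probs, labels, threshold)
    acc, f1 = accuracy_f1(tp, tn, fp, fn)
    return MetricsReport(
        acc=acc,
        f1=f1,
        auc=roc_auc(probs, labels),
        aupr=aupr(probs, labels),
        threshold=threshold,
        tp=tp, tn=tn, fp=fp, fn=fn,
    )


def mean_fold_metrics(reports) -> dict:
    """Average the headline metrics over per-fold reports."""
    keys = ("ACC", "F1", "AUC", "AUPR")
    return {k: float(np.mean([r.as_dict()[k] for r in reports])) for k in keys}
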