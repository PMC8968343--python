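"""Evaluation metrics for the five-category grader.

Per-class precision, recall and F1 come from the one-vs-rest reduction of the
5x5 confusion matrix (precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2TP/(2TP+FP+FN) -- note F1 is invariant under swapping FP and FN);
overall ACC is the fraction correct. One-vs-rest AUC is computed by the rank
(Mann-Whitney) statistic with half-weight ties -- the probability that a
positive case outranks a negative one -- and the macro AUC is the unweighted
mean over the classes present in the truth. The paired accuracy comparison
is a two-tailed paired-sample t-test on per-case correctness indicators.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CATEGORIES = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class EvalReport:
    """Confusion matrix (rows = truth), per-class metrics, ACC and AUCs."""

    confusion: np.ndarray
    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    acc: float
    n: int
    auc_per_class: dict[int, float] = field(default_factory=dict)
    auc_macro: float = math.nan

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": {str(c): {"precision": self.precision[c],
                                   "recall": self.recall[c],
                                   "f1": self.f1[c]} for c in CATEGORIES},
            "acc": self.acc,
            "n": self.n,
            "auc_per_class": {str(c): v for c, v in self.auc_per_class.items()},
            "auc_macro": self.auc_macro,
        }


def confusion_and_metrics(truth, pred) -> EvalReport:
    """Confusion matrix plus per-class precision/recall/F1 and overall ACC."""
    from sklearn.metrics import confusion_matrix

    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size < 1:
        raise ValueError("need at least one label pair")
    cm = confusion_matrix(truth, pred, labels=list(CATEGORIES))
    precision, recall, f1 = {}, {}, {}
    for k, c in enumerate(CATEGORIES):
        tp = cm[k, k]
        fp = cm[:, k].sum() - tp
        fn = cm[k, :].sum() - tp
        precision[c] = tp / (tp + fp) if tp + fp else 0.0
        recall[c] = tp / (tp + fn) if tp + fn else 0.0
        f1[c] = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    acc = float(np.trace(cm) / cm.sum())
    return EvalReport(cm, precision, recall, f1, acc, int(truth.size))


def _rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank statistic; ties count one half."""
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = stats.rankdata(scores)  # average ranks give half-weight ties
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    r_pos = ranks[:n_pos].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc_ovr(truth, scores) -> tuple[dict[int, float], float]:
    """One-vs-rest AUC per category and the macro (unweighted) mean.

    ``scores`` is (N, 5) with rows summing to 1. A class absent from the
    truth (or universal, leaving no negatives) has undefined AUC and is
    excluded from the macro mean with a warning.
    """
    truth = np.asarray(truth, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (truth.size, len(CATEGORIES)):
        raise ValueError(f"scores must be (n, 5), got {scores.shape}")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("score rows must sum to 1")
    aucs: dict[int, float] = {}
    for k, c in enumerate(CATEGORIES):
        pos = truth == c
        if pos.all() or not pos.any():
            warnings.warn(f"category {c} has no positives or no negatives; "
                          "AUC undefined and excluded from macro", stacklevel=2)
            continue
        aucs[c] = _rank_auc(scores[pos, k], scores[~pos, k])
    macro = float(np.mean(list(aucs.values()))) if aucs else math.nan
    return aucs, macro


def evaluate(truth, pred, scores=None) -> EvalReport:
    """Full report; AUC fields filled when probability scores are given."""
    report = confusion_and_metrics(truth, pred)
    if scores is None:
        return report
    aucs, macro = roc_auc_ovr(truth, scores)
    return EvalReport(report.confusion, report.precision, report.recall,
                      report.f1, report.acc, report.n, aucs, macro)


def paired_accuracy_test(correct_a, correct_b) -> tuple[float, float]:
    """Two-tailed paired t-test on per-case correctness indicators.

    Degenerate conventions: identical vectors give (0, 1); a constant
    non-zero difference has zero variance, reported as (+/-inf, 0) as the
    limit of the t statistic.
    """
    a = np.asarray(correct_a, dtype=float)
    b = np.asarray(correct_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("need at least two paired cases")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0:
        return math.copysign(math.inf, float(d.mean())), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
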