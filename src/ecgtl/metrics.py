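"""Evaluation metrics for the downstream protocols.

Single-label records are scored with the macro F1 (unweighted mean of
per-class F1). Multi-label records are scored with the averaged
class-wise ROC-AUC, the sample-centric Fmax, and the challenge-style
F(beta=2) and G(beta=2) measures computed from per-class confusion
counts and averaged over classes:

    F_beta = (1 + b^2) TP / ((1 + b^2) TP + FP + b^2 FN)
    G_beta = TP / (TP + FP + b FN)

Degenerate denominators contribute 0; a class absent from both truth
and prediction has F1 = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import f1_score, roc_auc_score

DEFAULT_GRID = np.round(np.arange(0.0, 1.0001, 0.01), 2)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Binary confusion counts from 0/1 arrays."""
    t = np.asarray(y_true, dtype=bool)
    p = np.asarray(y_pred, dtype=bool)
    return ConfusionCounts(tp=int((t & p).sum()), fp=int((~t & p).sum()),
                           fn=int((t & ~p).sum()), tn=int((~t & ~p).sum()))


def macro_f1(y_true, y_pred, classes: list | None = None
             ) -> tuple[float, dict]:
    """Macro F1 and per-class F1 over a fixed class set.

    A class absent from both truth and predictions scores 0 (so the
    macro average is comparable across runs with rare classes).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred differ in length")
    if classes is None:
        classes = sorted(set(y_true) | set(y_pred))
    per = f1_score(y_true, y_pred, labels=list(classes), average=None,
                   zero_division=0)
    per_class = {c: float(v) for c, v in zip(classes, per)}
    return float(np.mean(per)), per_class


def mean_classwise_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest ROC-AUC per class (midranks for ties), averaged.

    Classes without both a positive and a negative example are excluded
    from the average; if no class is scorable, raises ValueError.
    """
    y = np.atleast_2d(np.asarray(y_true))
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    if y.shape != s.shape:
        raise ValueError("y_true and scores must have the same shape")
    aucs = []
    for j in range(y.shape[1]):
        col = y[:, j]
        if 0 < col.sum() < len(col):
            aucs.append(roc_auc_score(col, s[:, j]))
    if not aucs:
        raise ValueError("no class has both positive and negative examples")
    return float(np.mean(aucs))


def f_max(y_true: np.ndarray, scores: np.ndarray,
          grid: np.ndarray = DEFAULT_GRID) -> float:
    """Sample-centric maximum F1 over decision thresholds.

    At each threshold, precision is averaged over samples with at least
    one predicted label and recall over all samples.
    """
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    y = np.atleast_2d(np.asarray(y_true)).astype(bool)
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    best = 0.0
    for t in grid:
        pred = s >= t
        any_pred = pred.any(axis=1)
        if not any_pred.any():
            continue
        inter = (pred & y).sum(axis=1)
        precision = float((inter[any_pred] / pred[any_pred].sum(axis=1)).mean())
        recall = float((inter / np.maximum(y.sum(axis=1), 1)).mean())
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return best


def f_beta_g_beta(y_true: np.ndarray, y_pred: np.ndarray, beta: float = 2.0
                  ) -> tuple[float, float]:
    """Challenge-style F(beta) and G(beta), averaged over classes."""
    y = np.atleast_2d(np.asarray(y_true)).astype(bool)
    p = np.atleast_2d(np.asarray(y_pred)).astype(bool)
    if y.shape != p.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    b2 = beta * beta
    fs, gs = [], []
    for j in range(y.shape[1]):
        c = confusion_counts(y[:, j], p[:, j])
        fden = (1 + b2) * c.tp + c.fp + b2 * c.fn
        gden = c.tp + c.fp + beta * c.fn
        fs.append((1 + b2) * c.tp / fden if fden > 0 else 0.0)
        gs.append(c.tp / gden if gden > 0 else 0.0)
    return float(np.mean(fs)), float(np.mean(gs))


def threshold_search(y_true: np.ndarray, scores: np.ndarray, metric,
                     grid: np.ndarray = DEFAULT_GRID) -> float:
    """Grid value maximising ``metric(y_true, scores >= t)``; ties go to
    the smallest threshold."""
    grid = np.asarray(grid)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    best_t, best_v = float(grid[0]), -np.inf
    for t in grid:
        v = metric(y_true, np.asarray(scores) >= t)
        if np.isscalar(v) is False:  # metrics returning tuples: use first element
            v = v[0]
        if v > best_v:
            best_t, best_v = float(t), float(v)
    return best_t
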