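"""Confusion-matrix metrics and ROC/AUC for binary fold evaluation.

The ROC is computed on continuous scores (higher score means more positive),
with one operating point per distinct threshold plus the (0,0) sentinel and
trapezoidal AUC. Tied scores collapse into one step, which is exactly the
half-credit (ties counted 1/2) concordance convention, so the trapezoidal
area equals the Mann-Whitney concordance probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FoldMetrics", "ROCResult", "confusion", "roc_curve"]


@dataclass(frozen=True)
class FoldMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass(eq=False)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def confusion(labels_true, labels_pred, positive_label=1) -> FoldMetrics:
    """Counts plus sensitivity (positive recall), specificity (negative
    recall) and accuracy."""
    t = np.asarray(labels_true)
    p = np.asarray(labels_pred)
    if t.size == 0:
        raise ValueError("confusion: empty input")
    if t.shape != p.shape:
        raise ValueError(f"confusion: length mismatch ({t.shape} vs {p.shape})")
    pos_t = t == positive_label
    pos_p = p == positive_label
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    if tp + fn == 0:
        raise ValueError("confusion: no positive ground-truth labels, sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("confusion: no negative ground-truth labels, specificity undefined")
    return FoldMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / t.size,
    )


def roc_curve(scores, labels_true, positive_label=1) -> ROCResult:
    """ROC operating points over all distinct score thresholds, with
    trapezoidal AUC."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(labels_true) == positive_label
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve: both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    t_sorted = t[order].astype(float)
    # last index of every tie group of equal scores
    distinct = np.r_[np.where(np.diff(s_sorted) != 0)[0], s_sorted.size - 1]
    tps = np.cumsum(t_sorted)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)
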