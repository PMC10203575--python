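"""Binary-classification metrics: ROC-AUC and threshold-based rates.

AUC uses the rank (Mann-Whitney) formulation with midrank tie handling,
as implemented by scikit-learn.  Threshold metrics follow the usual
confusion-matrix definitions; a metric whose denominator is zero is
reported as None rather than silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float


@dataclass
class MetricsReport:
    auc: float | None
    tpr: float | None
    fpr: float | None
    ppv: float | None
    npv: float | None
    recall: float | None


def roc_auc(labels, scores) -> float:
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    if len(labels) != len(scores):
        raise ValueError("labels and scores differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def confusion_metrics(labels, scores, threshold: float = 0.5, with_auc: bool = True):
    """Counts and rates at a fixed decision threshold (predict 1 iff score >= t)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(labels) != len(scores):
        raise ValueError("labels and scores differ in length")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    counts = ConfusionCounts(tp, tn, fp, fn, threshold)
    tpr = _ratio(tp, tp + fn)
    report = MetricsReport(
        auc=roc_auc(labels, scores) if with_auc and len(np.unique(labels)) == 2 else None,
        tpr=tpr,
        fpr=_ratio(fp, fp + tn),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        recall=tpr,
    )
    return counts, report


def roc_points(labels, scores):
    """(fpr, tpr, thresholds) arrays of the ROC curve, for optional TSV export."""
    return roc_curve(np.asarray(labels), np.asarray(scores))
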