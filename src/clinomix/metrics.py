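"""Classification metrics: accuracy, AUC and the Matthews correlation coefficient.

MCC and AUC are the metrics used for model comparison — both handle class
imbalance — while accuracy is reported for completeness.  AUC follows the
tie-aware Mann–Whitney form P(score⁺ > score⁻) + ½·P(tie) over all
positive–negative pairs.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["mcc", "mcc_from_labels", "auc", "accuracy"]


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    ``(tp·tn − fp·fn) / √((tp+fp)(tp+fn)(tn+fp)(tn+fn))``; defined as 0
    when any marginal is zero.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + tn + fp + fn < 1:
        raise ValueError("empty confusion matrix")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def mcc_from_labels(pred, y) -> float:
    pred = np.asarray(pred)
    y = np.asarray(y)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    return mcc(tp, tn, fp, fn)


def auc(scores, y) -> float:
    """Area under the ROC curve (Mann–Whitney form, ties count half)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, scores))


def accuracy(pred, y) -> float:
    pred = np.asarray(pred)
    y = np.asarray(y)
    return float((pred == y).mean())
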