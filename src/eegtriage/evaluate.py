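"""Model evaluation: one-vs-all ROC curves and the micro-average AUC.

Each class in turn is treated as positive against the other two; the
micro-average pools every (score, indicator) pair from the three binary
problems into a single sweep and is the headline metric reported for a
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .recording import CLASSES


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    positive: str  # class name or "micro"


def _finalize(fpr, tpr, thresholds, positive) -> ROCCurve:
    # sklearn emits the curve from (0,0) to (1,1) already; integrate by
    # the trapezoid rule
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
                    positive=positive)


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 2:
        raise ValueError("scores must be an n x n_classes matrix")
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels disagree in length")
    if scores.shape[0] < 2:
        raise ValueError("need at least 2 scored records")
    return scores, labels


def roc_one_vs_all(
    scores: np.ndarray,
    labels,
    positive_class: str,
    classes: list[str] | None = None,
) -> ROCCurve:
    """ROC for one class against the remaining ones."""
    scores, labels = _validate(scores, labels)
    classes = classes or [c for c in CLASSES if c in set(labels)]
    if positive_class not in classes:
        raise ValueError(f"unknown positive class {positive_class!r}")
    col = classes.index(positive_class)
    y = (labels == positive_class).astype(int)
    if y.min() == y.max():
        raise ValueError("labels contain a single class; ROC undefined")
    fpr, tpr, thr = roc_curve(y, scores[:, col])
    return _finalize(fpr, tpr, thr, positive_class)


def roc_micro_average(
    scores: np.ndarray, labels, classes: list[str] | None = None
) -> ROCCurve:
    """Pool all one-vs-all (score, indicator) pairs into one binary sweep."""
    scores, labels = _validate(scores, labels)
    classes = classes or [c for c in CLASSES if c in set(labels)]
    y = np.concatenate([(labels == c).astype(int) for c in classes])
    s = np.concatenate([scores[:, i] for i in range(len(classes))])
    if y.min() == y.max():
        raise ValueError("labels contain a single class; ROC undefined")
    fpr, tpr, thr = roc_curve(y, s)
    return _finalize(fpr, tpr, thr, "micro")


def evaluate_model(scores: np.ndarray, labels,
                   classes: list[str] | None = None) -> dict[str, float]:
    """Per-class and micro-average AUCs, keyed by class name and 'micro'."""
    scores, labels = _validate(scores, labels)
    classes = classes or [c for c in CLASSES if c in set(labels)]
    out = {}
    for c in classes:
        out[c] = roc_one_vs_all(scores, labels, c, classes).auc
    out["micro"] = roc_micro_average(scores, labels, classes).auc
    return out
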