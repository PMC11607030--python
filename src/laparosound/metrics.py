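"""Multiclass evaluation: confusion matrix, mAcc / mAP / mAR / F1.

Conventions (chosen to be mutually consistent with the harmonic-mean F1
relation on published adapter-study tables):

- mAcc is overall (micro) accuracy, trace(confusion) / n;
- mAP is the unweighted (macro) mean over classes of per-class precision;
- mAR is the macro mean of per-class recall;
- F1 = 2 * mAP * mAR / (mAP + mAR).

Classes absent from both labels and predictions are excluded from macro
means; a class predicted never but present in labels contributes its recall
normally, and a per-class precision with no predictions for that class is
counted as 0 with a warning (conservative, keeps the means defined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class EvalReport:
    """Confusion matrix (rows = true, cols = predicted) and derived metrics."""

    confusion: np.ndarray
    mAcc: float
    mAP: float
    mAR: float
    f1: float
    n_patches: int
    classes: tuple[str, ...] | None = None

    def round4(self) -> dict:
        """Display rounding used in result tables (4 decimal places)."""
        return {k: round(getattr(self, k), 4) for k in ("mAcc", "mAP", "mAR", "f1")}


def confusion_matrix(labels: np.ndarray, predictions: np.ndarray,
                     n_classes: int) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (labels, predictions), 1)
    return cm


def evaluate(predictions, labels, n_classes: int = 5,
             classes: tuple[str, ...] | None = None,
             macro_accuracy: bool = False) -> EvalReport:
    """Score integer class predictions against labels.

    ``macro_accuracy=True`` reports the per-class-averaged accuracy instead
    of the default overall accuracy.
    """
    predictions = np.asarray(predictions, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    if predictions.size == 0:
        raise ValueError("cannot evaluate empty prediction set")
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    if labels.min() < 0 or labels.max() >= n_classes or \
            predictions.min() < 0 or predictions.max() >= n_classes:
        raise ValueError(f"class indices must lie in [0, {n_classes})")

    cm = confusion_matrix(labels, predictions, n_classes)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    present = (support > 0) | (predicted > 0)

    tp = np.diag(cm).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(predicted > 0, tp / np.maximum(predicted, 1), 0.0)
        recall = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
    undefined_p = present & (predicted == 0) & (support > 0)
    if np.any(undefined_p):
        warnings.warn(
            f"{int(undefined_p.sum())} class(es) never predicted; "
            "their precision is counted as 0", stacklevel=2)

    mAP = float(precision[present].mean())
    mAR = float(recall[present].mean())
    if macro_accuracy:
        macc = float(recall[support > 0].mean())
    else:
        macc = float(tp.sum() / cm.sum())
    return EvalReport(confusion=cm, mAcc=macc, mAP=mAP, mAR=mAR,
                      f1=f1_from_pr(mAP, mAR), n_patches=int(cm.sum()),
                      classes=classes)


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 (with a warning) when both are 0."""
    if not (0 <= p <= 1 and 0 <= r <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if p + r == 0:
        warnings.warn("precision + recall = 0; F1 defined as 0", stacklevel=2)
        return 0.0
    return 2 * p * r / (p + r)


def summarize_across_testsets(maccs) -> tuple[float, float | None]:
    """Mean and sample (n-1) standard deviation of accuracies across test sets."""
    maccs = np.asarray(maccs, dtype=np.float64)
    if maccs.size < 1:
        raise ValueError("need at least one value")
    mean = float(maccs.mean())
    if maccs.size < 2:
        return mean, None
    return mean, float(maccs.std(ddof=1))
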