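"""Confusion matrices and classification metrics.

Conventions match the study's reporting: the confusion matrix is row-
normalised by true class, per-class accuracy is the class recall in percent,
"mean accuracy" is the unweighted arithmetic mean of the four recalls (the
printed per-class values pin this definition), and per-class mean confidence
averages the winning softmax probability over every sample *predicted* as
that class, correct or not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CLASSES

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion_matrix",
           "classification_metrics"]

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """4x4 counts, true class by row, in canonical class order."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    @property
    def percentages(self) -> np.ndarray:
        """Row-normalised percentages; all-zero rows stay zero."""
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(row > 0, 100.0 * self.counts / row, 0.0)
        return pct

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        data = self.percentages if percent else self.counts
        return pd.DataFrame(data, index=list(self.classes), columns=list(self.classes))


@dataclass
class MetricsReport:
    per_class_accuracy: dict        # recall, percent
    mean_accuracy: float            # unweighted mean of the recalls, percent
    per_class_f1: dict
    mean_f1: float
    per_class_confidence: dict      # mean winning probability per predicted class
    support: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class_accuracy": self.per_class_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "per_class_f1": self.per_class_f1,
            "mean_f1": self.mean_f1,
            "per_class_confidence": self.per_class_confidence,
            "support": self.support,
        }


def _as_indices(values, classes: tuple[str, ...]) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "UO":
        lookup = {c: i for i, c in enumerate(classes)}
        try:
            return np.array([lookup[v] for v in arr])
        except KeyError as exc:
            raise ValueError(f"unknown class label {exc.args[0]!r}") from exc
    idx = arr.astype(int)
    if idx.min() < 0 or idx.max() >= len(classes):
        raise ValueError("class index out of range")
    return idx


def confusion_matrix(predictions, labels,
                     classes: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    """Counts of (true class, predicted class) pairs.

    ``predictions`` and ``labels`` may be class names or indices; order
    within the sample lists is irrelevant.
    """
    pred = _as_indices(predictions, classes)
    true = _as_indices(labels, classes)
    if len(pred) != len(true):
        raise ValueError("predictions and labels differ in length")
    if len(pred) == 0:
        raise ValueError("empty input")
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (true, pred), 1)
    return ConfusionMatrix(counts, classes)


def classification_metrics(cm: ConfusionMatrix,
                           probabilities: np.ndarray | None = None,
                           predictions=None) -> MetricsReport:
    """Recall/precision/F1 per class, mean accuracy, and mean confidence.

    Mean accuracy is the unweighted mean of the per-class recalls (percent).
    F1 uses precision 0 (logged) for classes never predicted.  Confidence
    needs the per-sample softmax rows and the matching predictions; per-class
    confidence is the mean winning probability over samples predicted as the
    class.
    """
    counts = cm.counts
    k = len(cm.classes)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    supported = row > 0
    if supported.sum() < 2:
        raise ValueError("confusion matrix degenerate: fewer than two classes "
                         "have samples")
    diag = np.diag(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(supported, diag / np.maximum(row, 1), np.nan)
    precision = np.zeros(k)
    for i in range(k):
        if col[i] == 0:
            log.warning("class %r never predicted; precision set to 0",
                        cm.classes[i])
        else:
            precision[i] = diag[i] / col[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(supported & (precision + np.nan_to_num(recall) > 0),
                      2 * precision * np.nan_to_num(recall)
                      / (precision + np.nan_to_num(recall)), 0.0)

    confidence: dict = {}
    if probabilities is not None:
        probs = np.asarray(probabilities, dtype=float)
        if predictions is None:
            pred = probs.argmax(axis=1)
        else:
            pred = _as_indices(predictions, cm.classes)
        win = probs.max(axis=1)
        for i, cls in enumerate(cm.classes):
            sel = pred == i
            confidence[cls] = float(win[sel].mean()) if sel.any() else float("nan")

    # classes without samples are excluded from the means (their recall is
    # undefined); the per-class dicts keep every class for a stable schema
    acc = {cls: float(100.0 * recall[i]) for i, cls in enumerate(cm.classes)}
    return MetricsReport(
        per_class_accuracy=acc,
        mean_accuracy=float(100.0 * np.nanmean(recall)),
        per_class_f1={cls: float(f1[i]) for i, cls in enumerate(cm.classes)},
        mean_f1=float(f1[supported].mean()),
        per_class_confidence=confidence,
        support={cls: int(row[i]) for i, cls in enumerate(cm.classes)},
    )
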