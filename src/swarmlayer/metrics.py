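"""Confusion counts, the four reported scores, and small report helpers.

Label 1 (OSCC) is the positive class: precision and recall describe how
well carcinoma images are identified.  When a score's denominator is
zero the score is reported as 0 and flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

__all__ = [
    "Metrics",
    "confusion_and_metrics",
    "pct_accuracy_increase",
    "scatter_averages",
    "render_metrics_table",
]


@dataclass(frozen=True)
class Metrics:
    """Confusion counts and derived scores for a two-class problem."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def confusion_and_metrics(y_true, y_pred) -> Metrics:
    """Count the contingency table and compute accuracy/precision/recall/F1."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError(f"label vectors differ in shape: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("label vectors are empty")
    for arr, name in ((t, "y_true"), (p, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))
    tn = int(np.sum((t == 0) & (p == 0)))
    undefined: List[str] = []
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    if tp + fp == 0:
        precision = 0.0
        undefined.append("precision")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall = 0.0
        undefined.append("recall")
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1 = 0.0
        undefined.append("f1")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return Metrics(tp, fp, fn, tn, accuracy, precision, recall, f1,
                   undefined=tuple(undefined))


def pct_accuracy_increase(acc_without: float, acc_with: float) -> float:
    """Relative accuracy change, in percent, of adding the transform layer."""
    if acc_without == 0:
        raise ZeroDivisionError("baseline accuracy is zero")
    return 100.0 * (acc_with - acc_without) / acc_without


def scatter_averages(features) -> Tuple[float, float]:
    """(mean of the first half of a feature vector, mean of the rest).

    Used for two-dimensional scatter summaries of high-dimensional
    embeddings; odd lengths give the middle element to the first half.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector of at least 2 features")
    half = math.ceil(len(x) / 2)
    return float(np.mean(x[:half])), float(np.mean(x[half:]))


def render_metrics_table(rows) -> str:
    """Text table in the reported layout: model, layer, and the four
    scores rounded to 2 decimals.

    ``rows`` is an iterable of (model, layer, Metrics).
    """
    header = f"{'Model':<16}{'Layer':<8}{'Accuracy':>10}{'Precision':>11}{'Recall':>8}{'F1':>8}"
    lines = [header, "-" * len(header)]
    for model, layer, m in rows:
        lines.append(
            f"{model:<16}{layer:<8}{m.accuracy:>10.2f}{m.precision:>11.2f}"
            f"{m.recall:>8.2f}{m.f1:>8.2f}"
        )
    return "\n".join(lines)
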