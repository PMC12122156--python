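"""Patient-level evaluation metrics: confusion counts, accuracy, precision,
sensitivity, specificity, majority-class baseline and accuracy lift.

Fold averaging convention: metrics are computed per fold and averaged over
folds with equal weight; the reported spread is the population standard
deviation over folds. A metric with an undefined denominator (e.g. precision
with no positive predictions) is reported as missing (NaN), never as zero,
and skipped in fold averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Exact metric ratios; undefined denominators come back as NaN."""
    if counts.n == 0:
        raise ValueError("empty test set")
    return {
        "accuracy": (counts.tp + counts.tn) / counts.n,
        "precision": _ratio(counts.tp, counts.tp + counts.fp),
        "sensitivity": _ratio(counts.tp, counts.tp + counts.fn),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp),
    }


def baseline_accuracy(labels) -> float:
    """Accuracy of always predicting the majority class: max(p, 1 - p)."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("no labels")
    p = labels.mean()
    return float(max(p, 1.0 - p))


def lift(accuracy: float, baseline: float) -> float:
    """Model accuracy minus baseline accuracy."""
    return accuracy - baseline


def summarize_folds(fold_metrics: list[dict[str, float]]) -> dict[str, float]:
    """Equal-weight mean and population sd over folds, NaN-aware."""
    out: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array([m[name] for m in fold_metrics], dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:
            out[f"{name}_mean"] = float("nan")
            out[f"{name}_sd"] = float("nan")
        else:
            out[f"{name}_mean"] = float(finite.mean())
            out[f"{name}_sd"] = float(finite.std())  # population sd over folds
    return out
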