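"""ROC analysis, AUC and the minimum-distance operating point.

Scores are "more pain-like is larger"; a threshold ``t`` predicts pain
when ``score >= t``.  The curve has one point per distinct score value
(ties grouped) plus the (0, 0) endpoint at threshold +inf, and always ends
at (1, 1).  AUC is the trapezoidal area, which with grouped ties equals
the Mann-Whitney U statistic normalized by n1*n0 with ties counted 1/2.
The operating point reported alongside the curve is the one closest (in
Euclidean distance) to the ideal corner (FPR, TPR) = (0, 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ROCResult",
    "ConfusionMetrics",
    "roc_curve",
    "auc",
    "optimal_operating_point",
    "confusion_metrics",
    "plot_roc",
]


@dataclass
class ROCResult:
    """ROC sweep: descending thresholds, (FPR, TPR) points, AUC and the
    selected optimal operating point ``(threshold, fpr, tpr)``."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    optimal: tuple[float, float, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


@dataclass
class ConfusionMetrics:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy.

    A rate whose class is absent from the labels is reported as NaN — an
    explicit "undefined" marker, never silently 0.
    """

    sensitivity: float
    specificity: float
    accuracy: float


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 1 or labels.ndim != 1 or scores.shape != labels.shape:
        raise ValueError("scores and labels must be equal-length vectors")
    if not np.all(np.isin(labels, [0, 1])):
        raise ValueError("labels must be 0/1")
    return scores, labels.astype(int)


def roc_curve(scores, labels) -> ROCResult:
    """Build the ROC curve by sweeping the decision threshold.

    Raises if only one class is present, since neither rate is defined
    without both positives and negatives.
    """
    scores, labels = _validate_scores_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC needs both classes present; got "
            f"{n_pos} positives and {n_neg} negatives"
        )

    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    # last index of each tie group of equal scores
    distinct = np.nonzero(np.diff(s))[0]
    last = np.concatenate([distinct, [s.size - 1]])
    tps = np.cumsum(y)[last]
    fps = (last + 1) - tps

    thresholds = np.concatenate([[np.inf], s[last]])
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])

    area = float(np.trapezoid(tpr, fpr))
    result = ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=area, optimal=(0, 0, 0))
    result.optimal = optimal_operating_point(result)
    return result


def auc(roc: ROCResult) -> float:
    """Trapezoidal area under the ROC curve over the FPR axis."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def optimal_operating_point(roc: ROCResult) -> tuple[float, float, float]:
    """Curve point minimizing the distance to the ideal corner (0, 1).

    Ties are broken toward higher TPR, then toward the lower threshold.
    Returns ``(threshold, fpr, tpr)``.
    """
    d2 = roc.fpr**2 + (1.0 - roc.tpr) ** 2
    # lexsort keys: last key is primary
    best = np.lexsort((roc.thresholds, -roc.tpr, d2))[0]
    return (float(roc.thresholds[best]), float(roc.fpr[best]), float(roc.tpr[best]))


def confusion_metrics(predictions, labels) -> ConfusionMetrics:
    """Sensitivity, specificity and accuracy from binary predictions."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape or predictions.ndim != 1:
        raise ValueError("predictions and labels must be equal-length vectors")
    if not (np.all(np.isin(predictions, [0, 1])) and np.all(np.isin(labels, [0, 1]))):
        raise ValueError("predictions and labels must be 0/1")

    tp = int(np.sum((predictions == 1) & (labels == 1)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))

    sens = tp / (tp + fn) if (tp + fn) > 0 else math.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    acc = (tp + tn) / labels.size
    return ConfusionMetrics(sensitivity=sens, specificity=spec, accuracy=acc)


def plot_roc(rocs: dict[str, ROCResult], path: str | Path, title: str = "ROC") -> None:
    """Write an FPR-vs-TPR plot for one or more named curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, roc in rocs.items():
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC={roc.auc:.3f})")
        _, ofpr, otpr = roc.optimal
        ax.plot([ofpr], [otpr], marker="o", ls="none", color=ax.lines[-1].get_color())
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate (sensitivity)")
    ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
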