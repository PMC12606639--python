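"""Confusion-matrix accounting and binary classification scores.

The positive class is always *mutagen* (label 1).  Six scores are
reported: accuracy, balanced accuracy, precision, recall, F1 and the
Matthews correlation coefficient (MCC).  Zero-denominator cases follow
the usual conventions (see :func:`compute_metrics`), keeping every score
total so that cross-validation folds can always be aggregated.

:func:`reconstruct_confusion` inverts rounded precision/recall back to
the unique integer confusion matrix, which is useful for checking the
arithmetic consistency of published score tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_counts",
    "compute_metrics",
    "reconstruct_confusion",
    "AmbiguousReconstructionError",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts with mutagen (1) as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def errors(self) -> int:
        """Number of misclassified compounds (FP + FN)."""
        return self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    balanced_accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def rounded(self, decimals: int = 3) -> "MetricSet":
        return MetricSet(**{k: round(v, decimals) for k, v in asdict(self).items()})


def _as_binary(v, name: str) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"{name} must contain only 0/1 entries, got {sorted(uniq)}")
    return arr.astype(int)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Tally the 2x2 confusion matrix of two equal-length binary vectors."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape[0]} vs {yp.shape[0]}")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Compute the six scores from a confusion matrix.

    Conventions for empty denominators: precision is 0 when no positive
    prediction was made, recall is 0 when there is no positive sample,
    F1 is 0 when precision + recall is 0, and the MCC is 0 whenever a
    factor under the root vanishes.
    """
    if c.total == 0:
        raise ValueError("confusion matrix is empty")
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    accuracy = (tp + tn) / c.total
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    balanced = 0.5 * (sens + spec)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = sens
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    return MetricSet(
        accuracy=accuracy,
        balanced_accuracy=balanced,
        precision=precision,
        recall=recall,
        f1=f1,
        mcc=mcc,
    )


class AmbiguousReconstructionError(ValueError):
    """Several integer confusion matrices round to the given scores."""

    def __init__(self, solutions: list[ConfusionCounts]):
        self.solutions = solutions
        super().__init__(
            f"ambiguous: {len(solutions)} confusion matrices are consistent "
            f"with the rounded inputs: {solutions}"
        )


def reconstruct_confusion(
    precision_r: float,
    recall_r: float,
    n_pos: int,
    n_neg: int,
    decimals: int = 3,
) -> ConfusionCounts:
    """Invert rounded precision and recall to integer TP/FP/TN/FN.

    Searches exhaustively over TP in [0, n_pos] and FP in [0, n_neg] for
    count combinations whose precision and recall both round to the given
    values at ``decimals`` places.  Raises ``ValueError`` if no solution
    exists and :class:`AmbiguousReconstructionError` if more than one does.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    tol = 10.0 ** (-decimals) / 2 + 1e-12
    solutions: list[ConfusionCounts] = []
    for tp in range(n_pos + 1):
        recall = tp / n_pos
        if abs(recall - recall_r) >= tol:
            continue
        for fp in range(n_neg + 1):
            precision = tp / (tp + fp) if tp + fp else 0.0
            if abs(precision - precision_r) < tol:
                solutions.append(
                    ConfusionCounts(tp=tp, fp=fp, tn=n_neg - fp, fn=n_pos - tp)
                )
    if not solutions:
        raise ValueError("inconsistent inputs: no confusion matrix matches")
    if len(solutions) > 1:
        raise AmbiguousReconstructionError(solutions)
    return solutions[0]


def errors_from_accuracy(accuracy_r: float, n: int) -> int:
    """Misclassification count implied by a rounded accuracy on n samples."""
    if n <= 0:
        raise ValueError("n must be positive")
    return int(round((1.0 - accuracy_r) * n))
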