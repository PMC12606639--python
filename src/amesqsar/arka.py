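"""ARKA descriptors, class-expected regions and activity-cliff detection.

The ARKA construction condenses a descriptor matrix into two scalars per
compound.  Descriptors are min-max scaled to [0, 1] on the training set
and partitioned by which class they favor: D+ holds descriptors whose
training mean is higher among mutagens, D- those higher among
nonmutagens (ties are excluded).  For a compound, ARKA_1 is its average
over D+ and ARKA_2 its average over D-, each centered by the training
grand mean of that average so the training set sits at (0, 0) on
average.

Class-expected regions in the (ARKA_1, ARKA_2) plane:

    mutagen-expected:     ARKA_1 >  0.5 and ARKA_2 < -0.5
    nonmutagen-expected:  ARKA_1 < -0.5 and ARKA_2 >  0.5

A compound lying in the region expected for the *opposite* label is a
potential activity cliff; each cliff is paired with its closest compound
by the L1 distance |dARKA_1| + |dARKA_2| to suggest which neighbor may
explain the misbehavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArkaModel",
    "ArkaPoint",
    "fit_arka",
    "arka_scores",
    "detect_cliffs",
    "arka_table",
]


@dataclass
class ArkaModel:
    mins: np.ndarray
    maxs: np.ndarray
    d_pos: np.ndarray  # column indices favoring the mutagen class
    d_neg: np.ndarray  # column indices favoring the nonmutagen class
    grand_mean_pos: float
    grand_mean_neg: float
    column_names: list[str] = field(default_factory=list)


@dataclass
class ArkaPoint:
    id: str
    arka1: float
    arka2: float
    label: int
    is_cliff: bool = False
    nearest_id: str | None = None
    nearest_distance: float | None = None


def _values(X):
    v = X.values if hasattr(X, "values") else X
    return np.atleast_2d(np.asarray(v, dtype=float))


def _scale(m: ArkaModel, vals: np.ndarray) -> np.ndarray:
    span = m.maxs - m.mins
    span = np.where(span == 0, 1.0, span)
    return (vals - m.mins) / span


def fit_arka(X_train, y_train) -> ArkaModel:
    """Partition descriptors by class preference on the training set."""
    vals = _values(X_train)
    y = np.asarray(y_train, dtype=int).ravel()
    if vals.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    if vals.shape[0] < 2 or len(set(y.tolist())) < 2:
        raise ValueError("need both classes and more than one compound")
    mins = vals.min(axis=0)
    maxs = vals.max(axis=0)
    model = ArkaModel(
        mins=mins, maxs=maxs,
        d_pos=np.array([], dtype=int), d_neg=np.array([], dtype=int),
        grand_mean_pos=0.0, grand_mean_neg=0.0,
        column_names=list(getattr(X_train, "column_names", []) or []),
    )
    scaled = _scale(model, vals)
    mean_pos = scaled[y == 1].mean(axis=0)
    mean_neg = scaled[y == 0].mean(axis=0)
    model.d_pos = np.where(mean_pos > mean_neg)[0]
    model.d_neg = np.where(mean_neg > mean_pos)[0]
    if model.d_pos.size == 0 or model.d_neg.size == 0:
        raise ValueError("one of the ARKA descriptor sets is empty")
    model.grand_mean_pos = float(scaled[:, model.d_pos].mean(axis=1).mean())
    model.grand_mean_neg = float(scaled[:, model.d_neg].mean(axis=1).mean())
    return model


def arka_scores(m: ArkaModel, X, y, ids=None) -> list[ArkaPoint]:
    """Centered (ARKA_1, ARKA_2) per compound; training rows average to 0."""
    vals = _values(X)
    if vals.shape[1] != m.mins.shape[0]:
        raise ValueError("query width does not match the fitted model")
    if m.d_pos.size == 0 or m.d_neg.size == 0:
        raise ValueError("ARKA descriptor sets are empty")
    y = np.asarray(y, dtype=int).ravel()
    scaled = _scale(m, vals)
    arka1 = scaled[:, m.d_pos].mean(axis=1) - m.grand_mean_pos
    arka2 = scaled[:, m.d_neg].mean(axis=1) - m.grand_mean_neg
    if ids is None:
        ids = getattr(X, "row_ids", None) or [str(i) for i in range(vals.shape[0])]
    return [
        ArkaPoint(id=str(i), arka1=float(a1), arka2=float(a2), label=int(lab))
        for i, a1, a2, lab in zip(ids, arka1, arka2, y)
    ]


def _in_mutagen_region(pt: ArkaPoint) -> bool:
    return pt.arka1 > 0.5 and pt.arka2 < -0.5


def _in_nonmutagen_region(pt: ArkaPoint) -> bool:
    return pt.arka1 < -0.5 and pt.arka2 > 0.5


def detect_cliffs(points: list[ArkaPoint]) -> list[ArkaPoint]:
    """Flag compounds sitting in the opposite class's expected region.

    Returns the cliff points (mutated in place with their nearest
    neighbor by L1 distance in the ARKA plane).  Compounds outside both
    regions are never cliffs.
    """
    cliffs = []
    for pt in points:
        pt.is_cliff = (pt.label == 0 and _in_mutagen_region(pt)) or (
            pt.label == 1 and _in_nonmutagen_region(pt)
        )
        if pt.is_cliff:
            cliffs.append(pt)
    for pt in cliffs:
        best_d, best_id = None, None
        for other in points:
            if other is pt:
                continue
            d = abs(pt.arka1 - other.arka1) + abs(pt.arka2 - other.arka2)
            if best_d is None or d < best_d:
                best_d, best_id = d, other.id
        pt.nearest_id = best_id
        pt.nearest_distance = best_d
    return cliffs


def arka_table(points: list[ArkaPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": p.id,
                "arka1": p.arka1,
                "arka2": p.arka2,
                "label": p.label,
                "is_cliff": p.is_cliff,
                "nearest_id": p.nearest_id,
                "nearest_distance": p.nearest_distance,
            }
            for p in points
        ]
    )
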