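"""Pairwise OR-voting integration of single-family models.

Mirrors the any-positive logic of the Ames assay (and OECD TG471): a
compound is called mutagenic if *either* member model predicts it
mutagenic, and nonmutagenic only when both agree it is not.  Voting
operates on hard labels after thresholding, never on probabilities.

Consequences worth knowing: the integrated model's false negatives are
the intersection of the members' false negatives and its false positives
are the union of theirs, so recall can only go up and specificity can
only go down relative to the members.

The best pair is chosen on cross-validation metrics only — the
unweighted mean of CV accuracy, balanced accuracy and precision.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

from .neuralnet import TrainedNetwork, predict

__all__ = [
    "IntegratedModel",
    "SelectionReport",
    "or_vote",
    "enumerate_pairs",
    "select_best",
    "pair_matrix_tsv",
]


def or_vote(labels_a, labels_b) -> np.ndarray:
    """Elementwise any-positive vote over two binary label vectors."""
    a = np.asarray(labels_a, dtype=int).ravel()
    b = np.asarray(labels_b, dtype=int).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    for name, v in (("labels_a", a), ("labels_b", b)):
        if not set(np.unique(v).tolist()) <= {0, 1}:
            raise ValueError(f"{name} must be binary")
    return np.logical_or(a, b).astype(int)


@dataclass
class IntegratedModel:
    """Two member networks combined by the OR-vote rule."""

    member_a: TrainedNetwork
    member_b: TrainedNetwork

    @property
    def name(self) -> str:
        return f"{self.member_a.feature_family}-{self.member_b.feature_family}"

    def predict_labels(self, X_a, X_b) -> np.ndarray:
        """Predict from the two members' (differently featurized) inputs."""
        _, la = predict(self.member_a, X_a)
        _, lb = predict(self.member_b, X_b)
        return or_vote(la, lb)


def enumerate_pairs(families: list[str]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct families, in deterministic order.

    13 families yield C(13,2) = 78 integrated pairs.
    """
    if len(families) < 2:
        raise ValueError("need at least 2 families")
    if len(set(families)) != len(families):
        raise ValueError("duplicate family names in input")
    return list(itertools.combinations(families, 2))


@dataclass
class SelectionReport:
    # pair name -> (cv accuracy, cv balanced accuracy, cv precision, mean)
    per_pair: dict[str, tuple[float, float, float, float]]
    winner: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "winner": self.winner,
                "per_pair": {
                    k: {
                        "cv_accuracy": v[0],
                        "cv_balanced_accuracy": v[1],
                        "cv_precision": v[2],
                        "mean": v[3],
                    }
                    for k, v in self.per_pair.items()
                },
            },
            indent=2,
        )


def select_best(rows: dict[str, tuple[float, float, float]]) -> SelectionReport:
    """Pick the pair maximizing mean(CV accuracy, balanced accuracy, precision).

    Ties on the mean are broken by higher balanced accuracy, then by
    lexicographic pair name, so selection is deterministic.
    """
    if not rows:
        raise ValueError("no pairs to select from")
    per_pair = {}
    for name, vals in rows.items():
        if len(vals) != 3 or any(v is None for v in vals):
            raise ValueError(f"pair {name!r} is missing a metric")
        acc, bal, prec = map(float, vals)
        per_pair[name] = (acc, bal, prec, (acc + bal + prec) / 3.0)
    winner = min(per_pair, key=lambda k: (-per_pair[k][3], -per_pair[k][1], k))
    return SelectionReport(per_pair=per_pair, winner=winner)


def pair_matrix_tsv(
    families: list[str],
    upper: dict[tuple[str, str], float],
    lower: dict[tuple[str, str], float],
) -> str:
    """Render a two-triangle pair matrix as TSV.

    Balanced accuracy conventionally fills the upper triangle and
    precision the lower one; the diagonal is left blank.
    """

    def get(d, a, b):
        v = d.get((a, b), d.get((b, a)))
        return "" if v is None else f"{v:.3f}"

    lines = ["\t" + "\t".join(families)]
    for i, fa in enumerate(families):
        cells = []
        for j, fb in enumerate(families):
            if i == j:
                cells.append("")
            elif i < j:
                cells.append(get(upper, fa, fb))
            else:
                cells.append(get(lower, fa, fb))
        lines.append(fa + "\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"
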