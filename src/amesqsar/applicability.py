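"""Leverage-based applicability domain.

The applicability domain (AD) marks the region of feature space where a
QSAR model's predictions are considered reliable.  The leverage of a
query x against a training design X is the hat value

    h = x (X'X)^+ x'

compared with the critical value h* = 3(p + 1)/n, where p is the number
of features and n the number of training compounds.  Queries with
h > h* sit far from the training cloud and are flagged out-of-domain.

X'X is inverted with a Moore-Penrose pseudo-inverse (binary fingerprint
designs are routinely rank-deficient); the singular-value cutoff is the
machine-epsilon-scaled default, so in/out decisions are reproducible.
No intercept column is added: p counts the features as supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LeverageModel",
    "critical_hat",
    "fit_leverage",
    "hat_values",
    "ad_report",
]


def critical_hat(p: int, n: int) -> float:
    """Critical hat value h* = 3(p + 1)/n."""
    if p < 1 or n < 1:
        raise ValueError("p and n must be positive")
    return 3.0 * (p + 1) / n


@dataclass
class LeverageModel:
    core: np.ndarray  # (X'X)^+, p x p, symmetric
    p: int
    n: int
    h_star: float


def fit_leverage(X_train) -> LeverageModel:
    """Build the hat-value machinery from a cleaned training matrix."""
    vals = X_train.values if hasattr(X_train, "values") else np.asarray(X_train)
    vals = np.asarray(vals, dtype=float)
    if vals.ndim != 2 or vals.shape[1] == 0:
        raise ValueError("training matrix must be 2-D with at least one column")
    n, p = vals.shape
    if n < 2:
        raise ValueError("need more than one training row")
    gram = vals.T @ vals
    core = np.linalg.pinv(gram, hermitian=True)
    core = 0.5 * (core + core.T)  # enforce exact symmetry
    return LeverageModel(core=core, p=p, n=n, h_star=critical_hat(p, n))


def hat_values(m: LeverageModel, X_query):
    """Hat value per query row and the in-domain flag (h <= h*)."""
    vals = X_query.values if hasattr(X_query, "values") else np.asarray(X_query)
    vals = np.atleast_2d(np.asarray(vals, dtype=float))
    if vals.shape[1] != m.p:
        raise ValueError(f"query width {vals.shape[1]} does not match p={m.p}")
    h = np.einsum("ij,jk,ik->i", vals, m.core, vals)
    return h, h <= m.h_star


def ad_report(m: LeverageModel, X_query, ids=None) -> pd.DataFrame:
    """Per-compound applicability table: id, h, h_star, in_domain."""
    h, flags = hat_values(m, X_query)
    if ids is None:
        ids = getattr(X_query, "row_ids", None) or list(range(len(h)))
    return pd.DataFrame(
        {"id": ids, "h": h, "h_star": m.h_star, "in_domain": flags}
    )


def intersect_ad(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate outliers of two ADs (e.g. the integrated pair).

    A compound out of one domain may still be in the other, in which case
    the member model whose domain covers it can carry the prediction.
    """
    merged = report_a.merge(report_b, on="id", suffixes=("_a", "_b"))
    merged["n_domains"] = merged["in_domain_a"].astype(int) + merged[
        "in_domain_b"
    ].astype(int)
    return merged
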