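"""Importance algebra: emulated importances, diversity indexes, aggregation.

Linear models are harmonized with tree ensembles by transforming their
standardized (beta) coefficients and p-values into *emulated* feature
importances

    f_v = |beta_v| (1 - p_v)^gamma / sum_j |beta_j| (1 - p_j)^gamma

which, like impurity-based importances, form a probability vector.  The
emulated columns L and the actual columns M concatenate into F = (L | M);
the dot product with a stochastic model-weight vector W yields the
aggregated importance vector V = F @ W used to re-weight the data in the
unsupervised stages.

Diversity of a weight vector is summarized by the Gini coefficient (with
Lorenz-curve points) and Simpson's concentration index (Herfindahl index);
the reciprocal of the latter is the equivalent number of equally weighted
components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImportanceVector",
    "ImportanceMatrix",
    "DiversityStats",
    "emulate_importances",
    "gini_coefficient",
    "lorenz_curve",
    "simpson_index",
    "concat_importance_matrix",
    "aggregate_importances",
]

_TOL = 1e-9


@dataclass(frozen=True)
class ImportanceVector:
    """A labelled probability vector of per-feature weights."""

    labels: tuple[str, ...]
    weights: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or len(w) != len(self.labels):
            raise ValueError("weights must be 1-D and match labels")
        if np.any(w < -_TOL):
            raise ValueError("importance weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-6:
            raise ValueError(f"importance weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "weights", w)

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=list(self.labels))


@dataclass(frozen=True)
class ImportanceMatrix:
    """Column-stochastic matrix of importances (features x models)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray
    provenance: tuple[str, ...] = ()  # per column: "emulated" or "actual"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape must match labels")
        sums = v.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = [self.col_labels[i] for i in np.nonzero(np.abs(sums - 1) > 1e-6)[0]]
            raise ValueError(f"columns must sum to 1: {bad}")
        object.__setattr__(self, "values", v)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass(frozen=True)
class DiversityStats:
    gini: float
    simpson: float
    inv_simpson: float


def emulate_importances(
    beta: Sequence[float],
    pvalues: Sequence[float],
    gamma: float = 2.0,
    labels: Sequence[str] | None = None,
) -> ImportanceVector:
    """Transform signed coefficients and p-values into importances.

    Parameters
    ----------
    beta, pvalues
        Standardized coefficients and their p-values, equal length.
    gamma
        Discount exponent on (1 - p); 2 by default, 1 for a milder discount.

    Raises
    ------
    ValueError
        If every ``|beta| (1 - p)^gamma`` vanishes (e.g. all p-values are 1);
        a silent uniform vector would misrepresent the model.
    """
    b = np.asarray(beta, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    if b.shape != p.shape or b.ndim != 1:
        raise ValueError("beta and pvalues must be 1-D and equal length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(p))):
        raise ValueError("beta and pvalues must be finite")
    raw = np.abs(b) * (1.0 - p) ** gamma
    total = raw.sum()
    if total <= 0.0:
        raise ValueError(
            "all emulated importances are zero (every |beta|(1-p)^gamma vanished)"
        )
    labels = tuple(labels) if labels is not None else tuple(
        f"x{i}" for i in range(len(b))
    )
    return ImportanceVector(labels, raw / total, meta={"gamma": gamma})


def _check_weights(v) -> np.ndarray:
    x = np.asarray(v, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("expected a non-empty 1-D weight vector")
    if np.any(x < 0):
        raise ValueError("weights must be non-negative")
    if x.sum() <= 0:
        raise ValueError("weights must have a positive sum")
    return x


def lorenz_curve(v: Sequence[float]) -> np.ndarray:
    """Cumulative-share points of the Lorenz curve, ascending order.

    Returns an array of shape (n + 1,) starting at 0 and ending at 1.
    """
    x = np.sort(_check_weights(v))
    return np.concatenate([[0.0], np.cumsum(x) / x.sum()])


def gini_coefficient(v: Sequence[float]) -> float:
    """Gini coefficient of a non-negative weight vector.

    Uses the ascending-sort rank formula
    ``G = (2 sum_i i x_(i)) / (n sum x) - (n + 1)/n`` with ranks starting
    at 1 and no small-sample correction.
    """
    x = np.sort(_check_weights(v))
    n = len(x)
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum(i * x) / (n * x.sum()) - (n + 1.0) / n)


def simpson_index(v: Sequence[float]) -> DiversityStats:
    """Simpson concentration (sum of squared shares) and its reciprocal.

    The input is normalized to a probability vector internally, so any
    non-negative weight vector with positive sum is accepted.
    """
    x = _check_weights(v)
    p = x / x.sum()
    lam = float(np.sum(p**2))
    return DiversityStats(
        gini=gini_coefficient(x), simpson=lam, inv_simpson=1.0 / lam
    )


def concat_importance_matrix(
    L: pd.DataFrame, M: pd.DataFrame
) -> ImportanceMatrix:
    """Concatenate emulated (L) and actual (M) importances into F = (L | M).

    Row labels must agree exactly, in order; linear columns come first.
    """
    if list(L.index) != list(M.index):
        mismatched = sorted(set(L.index).symmetric_difference(M.index)) or [
            "(same set, different order)"
        ]
        raise ValueError(f"row labels of L and M differ: {mismatched}")
    F = pd.concat([L, M], axis=1)
    prov = ("emulated",) * L.shape[1] + ("actual",) * M.shape[1]
    return ImportanceMatrix(
        row_labels=tuple(F.index),
        col_labels=tuple(F.columns),
        values=F.to_numpy(dtype=float),
        provenance=prov,
    )


def aggregate_importances(
    F: ImportanceMatrix, W: Sequence[float]
) -> ImportanceVector:
    """Aggregate model importances: V = F @ W.

    ``W`` must be a stochastic vector over the columns of ``F``; because
    every column of F sums to one, V sums to one algebraically.
    """
    w = np.asarray(W, dtype=float)
    if w.shape != (len(F.col_labels),):
        raise ValueError(
            f"W has length {w.size}, F has {len(F.col_labels)} columns"
        )
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("W must be non-negative and sum to 1")
    V = F.values @ w
    # guard rounding drift so downstream stochastic-vector checks hold
    V = V / V.sum()
    return ImportanceVector(F.row_labels, V, meta={"models": F.col_labels})


def diversity_table(columns: pd.DataFrame) -> pd.DataFrame:
    """Gini / Simpson / reciprocal-Simpson for each column of a table."""
    rows = {}
    for name in columns:
        d = simpson_index(columns[name].to_numpy())
        rows[name] = {
            "gini": d.gini,
            "simpson": d.simpson,
            "inv_simpson": d.inv_simpson,
        }
    return pd.DataFrame(rows)
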