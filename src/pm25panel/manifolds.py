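"""Importance-weighted clustering and predictive manifold learning.

The full scaled array (no train/test split — unsupervised methods see all
rows) is used either as-is ("prior", equal feature weights) or with each
column multiplied by its aggregated importance V[j] ("posterior",
accuracy-weighted).  Affinity propagation clusters either array; six
dimensionality-reduction methods (PCA, MDS, t-SNE, isomap, LLE, factor
analysis) embed it.

A *predictive manifold* is a one-dimensional embedding standardized to
z-scores and sign-aligned with the observed mortality vector, treated as
a prediction of it.  The "MDS ecliptic" uses the plane spanned by the two
highest-variance coordinates of a 3-D MDS embedding, and an OLS blend of
all manifold predictions gives the composite unsupervised prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation
from sklearn.decomposition import PCA, FactorAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.manifold import MDS, TSNE, Isomap, LocallyLinearEmbedding

from .linear import AccuracyBlock, accuracy_block

__all__ = [
    "WeightedArray",
    "ClusterSolution",
    "Embedding",
    "ManifoldPrediction",
    "MANIFOLD_METHODS",
    "weight_columns",
    "cluster_affinity",
    "embed",
    "predictive_manifold",
    "mds_ecliptic",
    "unsupervised_ols_blend",
]

MANIFOLD_METHODS = ("pca", "mds", "tsne", "isomap", "lle", "factor")


@dataclass(frozen=True)
class WeightedArray:
    """A feature array with a recorded column weighting."""

    values: pd.DataFrame
    weighting_tag: str  # "prior" or "posterior"
    weight_vector: np.ndarray


@dataclass(frozen=True)
class ClusterSolution:
    labels: np.ndarray
    exemplars: np.ndarray  # row indices of the exemplars
    damping: float
    preference: float | None
    n_clusters: int

    def members(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


@dataclass(frozen=True)
class Embedding:
    method: str
    k: int
    coordinates: np.ndarray
    seed: int
    meta: Mapping[str, object]


@dataclass(frozen=True)
class ManifoldPrediction:
    method: str
    z: np.ndarray  # standardized, sign-aligned prediction
    accuracy: AccuracyBlock


def weight_columns(scaled_X: pd.DataFrame, weights=None) -> WeightedArray:
    """Scale each column by its importance weight (direct multiplication).

    ``weights=None`` tags the array as the equally weighted prior.
    """
    if weights is None:
        w = np.full(scaled_X.shape[1], 1.0 / scaled_X.shape[1])
        return WeightedArray(scaled_X.copy(), "prior", w)
    w = np.asarray(weights, dtype=float)
    if w.shape != (scaled_X.shape[1],):
        raise ValueError("weights must have one entry per column")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return WeightedArray(scaled_X * w, "posterior", w)


def _as_array(array) -> np.ndarray:
    if isinstance(array, WeightedArray):
        array = array.values
    return np.asarray(array, dtype=float)


def cluster_affinity(
    array,
    damping: float = 0.5,
    preference: float | None = None,
    seed: int = 1,
    max_iter: int = 500,
    convergence_iter: int = 15,
) -> ClusterSolution:
    """Affinity-propagation clustering on negative squared distances.

    ``preference=None`` uses the backend default, the median pairwise
    similarity.  Non-convergence raises with diagnostics instead of
    returning the degenerate all-singleton labelling.
    """
    X = _as_array(array)
    if len(X) < 2:
        raise ValueError("need at least 2 rows to cluster")
    ap = AffinityPropagation(
        damping=damping,
        preference=preference,
        random_state=seed,
        max_iter=max_iter,
        convergence_iter=convergence_iter,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ap.fit(X)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            raise RuntimeError(
                f"affinity propagation did not converge in {max_iter} "
                f"iterations (damping={damping}, preference={preference}); "
                "raise max_iter or damping"
            )
    exemplars = np.asarray(ap.cluster_centers_indices_)
    return ClusterSolution(
        labels=np.asarray(ap.labels_),
        exemplars=exemplars,
        damping=damping,
        preference=preference,
        n_clusters=len(exemplars),
    )


def embed(array, method: str, k: int, seed: int = 1, **method_params) -> Embedding:
    """Reduce to k dimensions with one of the six methods."""
    X = _as_array(array)
    n, p = X.shape
    if not 1 <= k < p:
        raise ValueError("k must satisfy 1 <= k < n_features")
    if n <= k:
        raise ValueError("need more rows than target dimensions")
    meta: dict[str, object] = {}
    if method == "pca":
        est = PCA(n_components=k, random_state=seed, **method_params)
        coords = est.fit_transform(X)
        meta["explained_variance_ratio"] = est.explained_variance_ratio_
    elif method == "factor":
        est = FactorAnalysis(n_components=k, random_state=seed, **method_params)
        coords = est.fit_transform(X)
    elif method == "mds":
        method_params.setdefault("normalized_stress", False)
        # classical (Torgerson) solution as SMACOF start: deterministic and
        # much closer to the global optimum than random restarts
        method_params.setdefault("init", "classical_mds")
        est = MDS(n_components=k, random_state=seed, **method_params)
        coords = est.fit_transform(X)
        meta["stress"] = float(est.stress_)
    elif method == "tsne":
        method_params.setdefault("perplexity", min(30.0, (n - 1) / 3))
        method_params.setdefault("init", "pca")
        est = TSNE(n_components=k, random_state=seed, **method_params)
        coords = est.fit_transform(X)
        meta["kl_divergence"] = float(est.kl_divergence_)
    elif method == "isomap":
        method_params.setdefault("n_neighbors", min(10, n - 1))
        est = Isomap(n_components=k, **method_params)
        coords = est.fit_transform(X)
    elif method == "lle":
        method_params.setdefault("n_neighbors", min(10, n - 1))
        est = LocallyLinearEmbedding(
            n_components=k, random_state=seed, **method_params
        )
        coords = est.fit_transform(X)
    else:
        raise ValueError(
            f"unknown method {method!r}; valid: {MANIFOLD_METHODS}"
        )
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError(f"{method} produced non-finite coordinates")
    return Embedding(method=method, k=k, coordinates=coords, seed=seed, meta=meta)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd <= 0:
        raise ValueError("zero-variance embedding cannot be standardized")
    return (v - v.mean()) / sd


def predictive_manifold(
    array, method: str, y, seed: int = 1, **method_params
) -> ManifoldPrediction:
    """One-dimensional embedding as a standardized prediction of y.

    The z-vector is flipped so that its correlation with y is
    non-negative (orientation of an embedding axis is arbitrary); this and
    the accuracy block are the only places the target touches the
    unsupervised pipeline.
    """
    y = np.asarray(y, dtype=float)
    emb = embed(array, method, k=1, seed=seed, **method_params)
    z = _standardize(emb.coordinates[:, 0])
    if np.corrcoef(z, y)[0, 1] < 0:
        z = -z
    return ManifoldPrediction(
        method=method, z=z, accuracy=accuracy_block(y, z)
    )


def mds_ecliptic(array, y, seed: int = 1, **method_params) -> ManifoldPrediction:
    """Prediction from the dominant plane of a 3-D MDS embedding.

    The two highest-variance MDS coordinates are combined by least
    squares against y; the fitted values are standardized.  If the two
    coordinates are collinear the combination falls back to one dimension
    with a warning.
    """
    y = np.asarray(y, dtype=float)
    X = _as_array(array)
    if len(X) <= 3:
        raise ValueError("need more than 3 rows for a 3-D MDS embedding")
    emb = embed(array, "mds", k=3, seed=seed, **method_params)
    order = np.argsort(emb.coordinates.var(axis=0))[::-1]
    plane = emb.coordinates[:, order[:2]]
    A = np.column_stack([np.ones(len(y)), plane])
    if np.linalg.matrix_rank(A) < 3:
        warnings.warn(
            "collinear MDS coordinates; falling back to one dimension",
            stacklevel=2,
        )
        A = A[:, :2]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    z = _standardize(A @ coef)
    if np.corrcoef(z, y)[0, 1] < 0:
        z = -z
    return ManifoldPrediction(
        method="mds_ecliptic", z=z, accuracy=accuracy_block(y, z)
    )


def unsupervised_ols_blend(
    predictions: Sequence[ManifoldPrediction], y
) -> ManifoldPrediction:
    """OLS of y on the stacked manifold predictions; the composite model.

    Collinear columns are dropped (pivoted QR) with a warning rather than
    failing; the fitted values are standardized like every other manifold
    prediction.
    """
    if len(predictions) < 2:
        raise ValueError("need at least 2 manifold predictions to blend")
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([p.z for p in predictions])
    A = np.column_stack([np.ones(len(y)), Z])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        import scipy.linalg

        _, _, piv = scipy.linalg.qr(A, pivoting=True)
        keep = sorted(piv[:rank])
        warnings.warn(
            f"dropping {A.shape[1] - rank} collinear manifold column(s)",
            stacklevel=2,
        )
        A = A[:, keep]
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    z = _standardize(A @ coef)
    if np.corrcoef(z, y)[0, 1] < 0:
        z = -z
    return ManifoldPrediction(
        method="unsupervised_ols", z=z, accuracy=accuracy_block(y, z)
    )
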