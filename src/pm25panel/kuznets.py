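"""Composite PCA indexes, environmental Kuznets curves and plot data.

An environmental Kuznets curve relates economic development to an
environmental harm — canonically an inverted U.  Here the x-axis is a
one-dimensional PCA composite of the 11 economic (or 12 health-based)
variables of the accuracy-weighted array, averaged per country, and the
y-axis is each country's mean standardized PM2.5 mortality.  Polynomial
fits of degree 1-4 are reported together with the pointwise average of
the degree-2/3/4 curves, whose curvature indicates the Kuznets shape.

Also here: 1-sd covariance ellipses summarizing cluster spread on a 2-D
plot, and "sundew" segment data comparing two competing predictions
observation by observation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datasets import ECONOMIC_FEATURES, GROUP_MAP, HEALTH_FEATURES
from .preprocess import aggregate_by_country

__all__ = [
    "CompositeIndex",
    "KuznetsCurve",
    "ClusterEllipse",
    "composite_index",
    "kuznets_curves",
    "cluster_ellipse",
    "sundew_plot_data",
]

#: sign anchors: the index is oriented to correlate positively with these
ANCHORS = {"economic": "real_gdp_pc", "health": "exposure"}


@dataclass(frozen=True)
class CompositeIndex:
    group: str
    variables: tuple[str, ...]
    values: pd.Series  # one value per country
    orientation_note: str


@dataclass(frozen=True)
class KuznetsCurve:
    x: np.ndarray
    y: np.ndarray
    fits: Mapping[int, np.ndarray]  # degree -> coefficients, highest first
    grid: np.ndarray
    average_curve: np.ndarray  # mean of degree-2/3/4 fitted curves on grid
    residual_sums: Mapping[int, float]

    def evaluate(self, degree: int, x) -> np.ndarray:
        return np.polyval(self.fits[degree], np.asarray(x, dtype=float))


@dataclass(frozen=True)
class ClusterEllipse:
    label: int
    center: tuple[float, float]
    axes: tuple[float, float]  # 1-sd half-axes, major first
    tilt: float  # radians, major axis vs x-axis
    degenerate: bool


def composite_index(
    weighted_array,
    group: str,
    entities: np.ndarray,
    anchor: str | None = None,
    aggregate_first: bool = False,
) -> CompositeIndex:
    """First principal component of a variable group, averaged by country.

    The PCA runs at observation level by default (297 rows), then the
    scores are averaged per country; ``aggregate_first=True`` averages
    before decomposing instead.  The sign is fixed so the index
    correlates positively with the anchor variable (real GDP per capita
    for the economic group, PM2.5 exposure for the health group).
    """
    if hasattr(weighted_array, "weighting_tag"):  # WeightedArray
        values = weighted_array.values
    else:
        values = weighted_array
    if group not in ("economic", "health"):
        raise ValueError("group must be 'economic' or 'health'")
    variables = tuple(
        c for c in values.columns if GROUP_MAP.get(c) == group
    )
    if not variables:
        raise ValueError(f"no {group} variables present in the array")
    block = values[list(variables)]
    anchor = anchor or ANCHORS[group]

    if aggregate_first:
        block = aggregate_by_country(block, entities)
        anchor_series = aggregate_by_country(
            values[[anchor]], entities
        )[anchor]
        entities = block.index.to_numpy()
    else:
        anchor_series = values[anchor]

    arr = block.to_numpy(dtype=float)
    if np.allclose(arr.std(axis=0), 0.0):
        raise ValueError(f"{group} slice is constant; PCA undefined")
    scores = PCA(n_components=1, random_state=0).fit_transform(arr)[:, 0]
    sign = 1.0
    if np.corrcoef(scores, anchor_series.to_numpy(dtype=float))[0, 1] < 0:
        sign, scores = -1.0, -scores

    per_country = (
        pd.Series(scores, index=np.asarray(entities))
        .groupby(level=0, sort=False)
        .mean()
    )
    return CompositeIndex(
        group=group,
        variables=variables,
        values=per_country,
        orientation_note=(
            f"sign {'flipped' if sign < 0 else 'kept'} so that "
            f"corr(index, {anchor}) > 0"
        ),
    )


def kuznets_curves(
    index: Sequence[float],
    mortality: Sequence[float],
    grid_points: int = 200,
) -> KuznetsCurve:
    """Polynomial fits of degree 1-4 plus the degree-2/3/4 average curve."""
    x = np.asarray(index, dtype=float)
    y = np.asarray(mortality, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("index and mortality must be equal-length vectors")
    if len(x) < 5:
        raise ValueError("need at least 5 points for a quartic fit")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    fits: dict[int, np.ndarray] = {}
    residual_sums: dict[int, float] = {}
    for d in (1, 2, 3, 4):
        coef = np.polyfit(x, y, deg=d)
        fits[d] = coef
        residual_sums[d] = float(np.sum((y - np.polyval(coef, x)) ** 2))
    grid = np.linspace(x.min(), x.max(), grid_points)
    average = np.mean(
        [np.polyval(fits[d], grid) for d in (2, 3, 4)], axis=0
    )
    return KuznetsCurve(
        x=x, y=y, fits=fits, grid=grid, average_curve=average,
        residual_sums=residual_sums,
    )


def cluster_ellipse(
    points: np.ndarray, labels: np.ndarray, min_axis: float = 1e-3
) -> list[ClusterEllipse]:
    """1-sd covariance ellipse per cluster on a 2-D scatter.

    Clusters with fewer than 3 points or zero variance get a
    minimal-width fallback ellipse, flagged as degenerate.
    """
    pts = np.asarray(points, dtype=float)
    labs = np.asarray(labels)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    if len(pts) != len(labs):
        raise ValueError("labels must match points")
    uniq = pd.unique(labs)
    if len(uniq) == 0:
        raise ValueError("empty label set")
    out = []
    for lab in uniq:
        sub = pts[labs == lab]
        center = (float(sub[:, 0].mean()), float(sub[:, 1].mean()))
        degenerate = len(sub) < 3
        if not degenerate:
            cov = np.cov(sub.T)
            vals, vecs = np.linalg.eigh(cov)
            degenerate = vals[0] <= 0 or not np.all(np.isfinite(vals))
        if degenerate:
            spread = float(sub.std()) if len(sub) > 1 else 0.0
            a = max(spread, min_axis)
            out.append(
                ClusterEllipse(
                    label=lab, center=center, axes=(a, min_axis),
                    tilt=0.0, degenerate=True,
                )
            )
            continue
        major = vecs[:, 1]
        out.append(
            ClusterEllipse(
                label=lab,
                center=center,
                axes=(float(np.sqrt(vals[1])), float(np.sqrt(vals[0]))),
                tilt=float(np.arctan2(major[1], major[0])),
                degenerate=False,
            )
        )
    return out


def sundew_plot_data(obs, pred_a, pred_b) -> pd.DataFrame:
    """Per-observation segments comparing two competing predictions."""
    o = np.asarray(obs, dtype=float)
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if not (o.shape == a.shape == b.shape) or o.ndim != 1:
        raise ValueError("obs, pred_a and pred_b must be equal-length vectors")
    return pd.DataFrame(
        {
            "obs": o,
            "pred_a": a,
            "pred_b": b,
            "dist_a": np.abs(a - o),
            "dist_b": np.abs(b - o),
        }
    )


def group_weight_shares(V) -> dict[str, float]:
    """Economic vs health share of an aggregated importance vector."""
    series = V.as_series() if hasattr(V, "as_series") else pd.Series(V)
    econ = float(series[[f for f in series.index if f in ECONOMIC_FEATURES]].sum())
    health = float(series[[f for f in series.index if f in HEALTH_FEATURES]].sum())
    return {"economic": econ, "health": health}
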