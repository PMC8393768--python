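"""LOESS + polynomial-spline imputation of panel time series.

Each entity's series for a feature with missing years is handled
independently: a LOESS smoother (tricube-weighted local linear fits over
the ``ceil(frac * n)`` nearest observed time points) is evaluated at the
observed times, a polynomial spline is drawn through the smoothed points,
and the spline fills the gaps — interior by interpolation, leading and
trailing by extrapolation.

The spline order is configured per feature (the reference pattern uses a
linear spline for PM2.5 exposure and cubic splines for COPD and tracheal
mortality).  When the requested order is not supportable (too few observed
points) or produces values far outside the observed range (beyond
``min - 1.5 * range`` / ``max + 1.5 * range``), the order is reduced by
one and retried, with a floor at 1; every fallback is recorded in the
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline

from .synthetic import PanelDataset

__all__ = ["ImputationReport", "loess_smooth", "spline_complete", "impute_panel"]

#: default spline order per feature; features not listed use DEFAULT_ORDER
REFERENCE_ORDERS = {"exposure": 1, "copd_death": 3, "tracheal_death": 3}
DEFAULT_ORDER = 3


@dataclass
class ImputationReport:
    """Record of every imputed cell: (entity, year, value, spline order)."""

    cells: dict[str, list[tuple[str, int, float, int]]] = field(
        default_factory=dict
    )
    fallbacks: list[tuple[str, str, int, int]] = field(default_factory=list)
    # fallbacks: (entity, feature, requested_order, used_order)

    @property
    def totals(self) -> dict[str, int]:
        return {feat: len(rows) for feat, rows in self.cells.items()}

    def add(self, feature: str, entity: str, year: int, value: float, order: int):
        self.cells.setdefault(feature, []).append((entity, year, value, order))

    def to_dict(self) -> dict:
        return {
            "totals": self.totals,
            "cells": {
                f: [
                    {"entity": e, "year": int(y), "value": float(v), "order": int(k)}
                    for e, y, v, k in rows
                ]
                for f, rows in self.cells.items()
            },
            "fallbacks": [
                {"entity": e, "feature": f, "requested": r, "used": u}
                for e, f, r, u in self.fallbacks
            ],
        }


def loess_smooth(times, values, frac: float = 0.5) -> np.ndarray:
    """Tricube-weighted local linear smoothing at the observed times.

    For each time point, the ``k = max(ceil(frac * n), 2)`` nearest
    observed points are fitted by weighted least squares with tricube
    weights ``(1 - (d / d_max)^3)^3``; the smoothed value is the local fit
    evaluated at that point.  Windows whose weights collapse onto a single
    point fall back to the tricube-weighted mean.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and equal length")
    n = len(t)
    if n < 2:
        raise ValueError("LOESS needs at least 2 observed points")
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    k = max(int(np.ceil(frac * n)), 2)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        if dmax == 0.0:
            w = np.ones(len(idx))
        else:
            w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        ts, ys = t[idx], y[idx]
        swx = np.sum(w * ts)
        sw = np.sum(w)
        sxx = np.sum(w * (ts - swx / sw) ** 2)
        if sxx <= 1e-12 * max(1.0, np.sum(w * ts**2)):
            out[i] = np.sum(w * ys) / sw  # degenerate window
            continue
        A = np.column_stack([np.ones(len(ts)), ts])
        WA = A * w[:, None]
        beta = np.linalg.solve(A.T @ WA, WA.T @ ys)
        out[i] = beta[0] + beta[1] * t[i]
    return out


def spline_complete(times, values, order: int, eval_times) -> np.ndarray:
    """Evaluate an order-``order`` interpolating spline on a full grid.

    The spline passes through the given (time, value) points exactly, so
    values at observed times are preserved when no prior smoothing was
    applied; points outside the observed span are extrapolated.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    grid = np.asarray(eval_times, dtype=float)
    if len(t) == 0:
        raise ValueError("cannot spline an empty series")
    if not 1 <= order <= 3:
        raise ValueError("spline order must be 1, 2 or 3")
    if len(t) < order + 1:
        raise ValueError(
            f"order-{order} spline needs at least {order + 1} points, got {len(t)}"
        )
    srt = np.argsort(t)
    spline = InterpolatedUnivariateSpline(t[srt], y[srt], k=order, ext=0)
    return spline(grid)


def _complete_series(t_obs, v_obs, t_all, order, frac, report, entity, feature):
    """Smooth, spline and fill one entity series; returns values at t_all."""
    obs_min, obs_max = v_obs.min(), v_obs.max()
    rng_width = obs_max - obs_min
    lo, hi = obs_min - 1.5 * rng_width, obs_max + 1.5 * rng_width
    smoothed = loess_smooth(t_obs, v_obs, frac=frac)
    used = order
    while True:
        if len(t_obs) >= used + 1:
            filled = spline_complete(t_obs, smoothed, used, t_all)
            if np.all((filled >= lo) & (filled <= hi)):
                break
        if used == 1:
            # linear floor: accept whatever it produced
            filled = spline_complete(t_obs, smoothed, 1, t_all)
            break
        used -= 1
    if used != order:
        report.fallbacks.append((entity, feature, order, used))
    return filled, used


def impute_panel(
    panel: PanelDataset,
    order_map: dict[str, int] | None = None,
    frac: float = 0.5,
    default_order: int = DEFAULT_ORDER,
) -> tuple[PanelDataset, ImputationReport]:
    """Fill every masked cell, entity by entity; observed cells unchanged.

    Raises
    ------
    ValueError
        If some entity has no observed value at all for a masked feature.
    """
    orders = dict(REFERENCE_ORDERS)
    orders.update(order_map or {})
    out = panel.copy()
    report = ImputationReport()
    mask = out.missing_mask
    for feature in out.X.columns[mask.any(axis=0).to_numpy()]:
        order = orders.get(feature, default_order)
        col = out.X.columns.get_loc(feature)
        for entity in out.entities:
            rows = np.nonzero(out.entity == entity)[0]
            miss = mask.iloc[rows, col].to_numpy()
            if not miss.any():
                continue
            if miss.all():
                raise ValueError(
                    f"entity {entity!r} has no observed values for {feature!r}"
                )
            years = out.year[rows].astype(float)
            vals = out.X.iloc[rows, col].to_numpy(dtype=float)
            filled, used = _complete_series(
                years[~miss], vals[~miss], years, order, frac, report,
                entity, feature,
            )
            for r, yr, v, was_missing in zip(rows, out.year[rows], filled, miss):
                if was_missing:
                    out.X.iloc[r, col] = v
                    report.add(feature, entity, int(yr), float(v), used)
    return out, report
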