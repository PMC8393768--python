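"""Splitting, leakage-safe standardization and country aggregation.

The supervised stages use a seeded 75/25 shuffle split (297 rows ->
223 train / 74 test) and z-score both partitions with means and standard
deviations fitted on the training rows only (population 1/n convention).
The unsupervised stages operate on all rows, standardized with the same
train-fitted scale, and optionally aggregated to one mean row per country.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PanelDataset

__all__ = ["ScaledSplit", "split_panel", "standard_scale", "scale_split",
           "aggregate_by_country"]


@dataclass
class ScaledSplit:
    """Train/test partition of a panel, standardized on the train scale."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    feature_names: tuple[str, ...]
    X_train: pd.DataFrame
    X_test: pd.DataFrame
    y_train: np.ndarray
    y_test: np.ndarray
    x_mean: pd.Series
    x_sd: pd.Series
    y_mean: float
    y_sd: float
    full_scaled_X: pd.DataFrame
    full_scaled_y: np.ndarray
    entity: np.ndarray
    year: np.ndarray
    instrument_name: str
    welfare_train: np.ndarray | None = None
    welfare_test: np.ndarray | None = None
    full_scaled_welfare: np.ndarray | None = None
    welfare_mean: float | None = None
    welfare_sd: float | None = None

    @property
    def entity_train(self) -> np.ndarray:
        return self.entity[self.train_idx]

    @property
    def entity_test(self) -> np.ndarray:
        return self.entity[self.test_idx]

    @property
    def year_train(self) -> np.ndarray:
        return self.year[self.train_idx]

    @property
    def year_test(self) -> np.ndarray:
        return self.year[self.test_idx]

    def scaler_to_dict(self) -> dict:
        """Scaler parameters and index sets, for an exact rerun."""
        return {
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "x_mean": self.x_mean.to_dict(),
            "x_sd": self.x_sd.to_dict(),
            "y_mean": self.y_mean,
            "y_sd": self.y_sd,
        }


def split_panel(
    panel: PanelDataset, test_fraction: float = 0.25, seed: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform shuffle split; floor(n * test_fraction) test rows."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n = panel.n_rows
    n_test = int(np.floor(n * test_fraction))
    if n_test < 1 or n - n_test < 1:
        raise ValueError("split would leave an empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def standard_scale(
    train_rows: pd.DataFrame, test_rows: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """z-score both partitions with train-only mean and population sd."""
    mu = train_rows.mean()
    sd = pd.Series(
        train_rows.to_numpy(dtype=float).std(axis=0, ddof=0),
        index=train_rows.columns,
    )
    constant = sd.index[sd <= 0.0].tolist()
    if constant:
        raise ValueError(f"zero-variance train column(s): {constant}")
    return (train_rows - mu) / sd, (test_rows - mu) / sd, mu, sd


def scale_split(
    panel: PanelDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    scale: bool = True,
) -> ScaledSplit:
    """Assemble a :class:`ScaledSplit` from a panel and an index split.

    ``scale=False`` keeps raw units (identity scaler) — useful when true
    generator coefficients must be recovered without rescaling.
    """
    if panel.X.isna().any().any():
        raise ValueError("panel still has missing values; impute first")
    overlap = np.intersect1d(train_idx, test_idx)
    if overlap.size:
        raise ValueError("train and test indices overlap")

    X, y = panel.X, np.asarray(panel.y, dtype=float)
    Xtr, Xte = X.iloc[train_idx], X.iloc[test_idx]
    if scale:
        Xtr_s, Xte_s, mu, sd = standard_scale(Xtr, Xte)
        y_mu = float(y[train_idx].mean())
        y_sd = float(y[train_idx].std(ddof=0))
        if y_sd <= 0:
            raise ValueError("target is constant on the train partition")
        full_X = (X - mu) / sd
        full_y = (y - y_mu) / y_sd
    else:
        Xtr_s, Xte_s = Xtr.copy(), Xte.copy()
        mu = pd.Series(0.0, index=X.columns)
        sd = pd.Series(1.0, index=X.columns)
        y_mu, y_sd = 0.0, 1.0
        full_X, full_y = X.copy(), y.copy()

    kw: dict = {}
    if panel.welfare is not None:
        w = np.asarray(panel.welfare, dtype=float)
        w_mu = float(w[train_idx].mean()) if scale else 0.0
        w_sd = float(w[train_idx].std(ddof=0)) if scale else 1.0
        if w_sd <= 0:
            raise ValueError("welfare is constant on the train partition")
        w_s = (w - w_mu) / w_sd
        kw = {
            "welfare_train": w_s[train_idx],
            "welfare_test": w_s[test_idx],
            "full_scaled_welfare": w_s,
            "welfare_mean": w_mu,
            "welfare_sd": w_sd,
        }

    return ScaledSplit(
        train_idx=np.asarray(train_idx),
        test_idx=np.asarray(test_idx),
        feature_names=tuple(X.columns),
        X_train=Xtr_s,
        X_test=Xte_s,
        y_train=(y[train_idx] - y_mu) / y_sd,
        y_test=(y[test_idx] - y_mu) / y_sd,
        x_mean=mu,
        x_sd=sd,
        y_mean=y_mu,
        y_sd=y_sd,
        full_scaled_X=full_X,
        full_scaled_y=full_y,
        entity=panel.entity,
        year=panel.year,
        instrument_name=panel.instrument_name,
        **kw,
    )


def aggregate_by_country(
    full_scaled_X: pd.DataFrame, entities: np.ndarray
) -> pd.DataFrame:
    """Mean row per entity, first-appearance order preserved."""
    if len(entities) != len(full_scaled_X):
        raise ValueError("entities must label every row of the array")
    order = pd.unique(np.asarray(entities))
    grouped = full_scaled_X.groupby(np.asarray(entities), sort=False).mean()
    return grouped.loc[order]
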