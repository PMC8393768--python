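"""Tree-ensemble regressors with exhaustive cross-validated grid search.

Six models: random forest, extra trees, AdaBoost (depth-1 stumps),
scikit-learn gradient boosting, XGBoost and LightGBM.  All train on the
standardized train partition only, use a fixed seed (default 1), and
expose impurity-based feature importances renormalized to sum to one.

Grid search is an explicit loop over the supplied grid in insertion
order: every combination is scored by mean RMSE over seeded K-fold CV and
the first minimum wins, so tie-breaking is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from lightgbm import LGBMRegressor
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .linear import AccuracyBlock, accuracy_block
from .preprocess import ScaledSplit

__all__ = ["EnsembleFit", "grid_search_cv", "fit_ensemble", "DEFAULT_GRIDS",
           "MODEL_IDS"]

MODEL_IDS = (
    "random_forest",
    "extra_trees",
    "adaboost",
    "gradient_boosting",
    "xgboost",
    "lightgbm",
)

#: modest default grids; forests tune the two hyperparameters that matter
#: for them (feature-subset size and tree depth), boosters tune learning
#: rate, depth and round count
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {
        "max_depth": [3, 5, 10, None],
        "max_features": ["sqrt", 0.33, 1.0],
    },
    "extra_trees": {
        "max_depth": [3, 5, 10, None],
        "max_features": ["sqrt", 0.33, 1.0],
    },
    "adaboost": {
        "learning_rate": [0.05, 0.1, 0.5],
        "n_estimators": [100, 300],
    },
    "gradient_boosting": {
        "learning_rate": [0.05, 0.1],
        "max_depth": [2, 3, 4],
        "n_estimators": [200, 500],
    },
    "xgboost": {
        "learning_rate": [0.05, 0.1],
        "max_depth": [2, 3, 4],
        "n_estimators": [200, 500],
    },
    "lightgbm": {
        "learning_rate": [0.05, 0.1],
        "max_depth": [2, 3, 4],
        "n_estimators": [200, 500],
    },
}


def make_estimator(model_id: str, params: Mapping | None = None, seed: int = 1):
    """Instantiate one of the six regressors with shared defaults."""
    params = dict(params or {})
    if model_id == "random_forest":
        params.setdefault("n_estimators", 500)
        return RandomForestRegressor(random_state=seed, **params)
    if model_id == "extra_trees":
        params.setdefault("n_estimators", 500)
        return ExtraTreesRegressor(random_state=seed, **params)
    if model_id == "adaboost":
        params.setdefault("n_estimators", 300)
        stump_depth = params.pop("stump_depth", 1)
        return AdaBoostRegressor(
            estimator=DecisionTreeRegressor(max_depth=stump_depth),
            random_state=seed,
            **params,
        )
    if model_id == "gradient_boosting":
        params.setdefault("n_estimators", 500)
        return GradientBoostingRegressor(random_state=seed, **params)
    if model_id == "xgboost":
        params.setdefault("n_estimators", 500)
        return XGBRegressor(random_state=seed, verbosity=0, **params)
    if model_id == "lightgbm":
        params.setdefault("n_estimators", 500)
        return LGBMRegressor(random_state=seed, verbose=-1, **params)
    raise ValueError(f"unknown model_id {model_id!r}; valid ids: {MODEL_IDS}")


@dataclass
class EnsembleFit:
    model_id: str
    feature_names: tuple[str, ...]
    best_params: dict
    importances: np.ndarray
    train_pred: np.ndarray
    test_pred: np.ndarray
    accuracy: Mapping[str, AccuracyBlock]
    seed: int

    def __post_init__(self) -> None:
        w = np.asarray(self.importances, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("importances must be non-negative and sum to 1")


def _expand_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    """All combinations, varying the *last* key fastest (insertion order)."""
    keys = list(grid.keys())
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(grid[k] for k in keys))
    ]


def grid_search_cv(
    model_id: str,
    grid: Mapping[str, Sequence],
    X,
    y,
    folds: int = 5,
    seed: int = 1,
) -> dict:
    """Exhaustive grid search minimizing mean CV RMSE.

    Ties are broken by the first occurrence in grid order (strict '<'
    when comparing later candidates to the incumbent).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not grid:
        raise ValueError("empty grid")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > len(y):
        raise ValueError(f"{folds} folds exceed {len(y)} train rows")
    candidates = _expand_grid(grid)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_idx = list(splitter.split(X))
    best_params, best_rmse = None, np.inf
    for params in candidates:
        proto = make_estimator(model_id, params, seed=seed)
        rmses = []
        for tr, va in fold_idx:
            est = clone(proto)
            est.fit(X[tr], y[tr])
            err = est.predict(X[va]) - y[va]
            rmses.append(np.sqrt(np.mean(err**2)))
        mean_rmse = float(np.mean(rmses))
        if mean_rmse < best_rmse:
            best_params, best_rmse = params, mean_rmse
    return dict(best_params)


def fit_ensemble(
    model_id: str,
    split: ScaledSplit,
    params: Mapping | None = None,
    seed: int = 1,
) -> EnsembleFit:
    """Train one tree-ensemble regressor on the scaled train partition."""
    est = make_estimator(model_id, params, seed=seed)
    Xtr = split.X_train.to_numpy(dtype=float)
    Xte = split.X_test.to_numpy(dtype=float)
    est.fit(Xtr, split.y_train)
    raw = np.asarray(est.feature_importances_, dtype=float)
    total = raw.sum()
    if total <= 0:
        raise ValueError(f"{model_id} produced an all-zero importance vector")
    train_pred = est.predict(Xtr)
    test_pred = est.predict(Xte)
    return EnsembleFit(
        model_id=model_id,
        feature_names=split.feature_names,
        best_params=dict(params or {}),
        importances=raw / total,
        train_pred=np.asarray(train_pred, dtype=float),
        test_pred=np.asarray(test_pred, dtype=float),
        accuracy={
            "train": accuracy_block(split.y_train, train_pred),
            "test": accuracy_block(split.y_test, test_pred),
        },
        seed=seed,
    )
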