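"""Two-level stacking generalization with a tree-ensemble blender.

Level 0 stacks the train/test predictions of any mix of linear and
tree-ensemble fits into prediction matrices (one column per model).  The
level-1 blender — a random forest or extra trees regressor — trains on
the in-sample train predictions, emits meta-predictions for both
partitions, and exposes its feature importances as the model-weight
vector W used to aggregate the grand importance matrix F = (L | M).

Training the blender on in-sample level-0 predictions is deliberately
optimistic; callers wanting out-of-fold stacking can assemble the level-0
matrix from out-of-fold predictions and pass it in unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import ExtraTreesRegressor, RandomForestRegressor

from .ensembles import EnsembleFit
from .importance import DiversityStats, simpson_index
from .linear import AccuracyBlock, LinearFit, accuracy_block

__all__ = ["Level0Matrix", "BlenderFit", "assemble_level0", "fit_blender",
           "blender_diversity"]

BLENDER_IDS = ("extra_trees", "random_forest")


@dataclass(frozen=True)
class Level0Matrix:
    model_ids: tuple[str, ...]
    train: np.ndarray  # n_train x m
    test: np.ndarray  # n_test x m

    def __post_init__(self) -> None:
        if self.train.shape[1] != self.test.shape[1]:
            raise ValueError("train/test column counts differ")
        if not (np.all(np.isfinite(self.train)) and np.all(np.isfinite(self.test))):
            raise ValueError("level-0 predictions must be finite")


@dataclass
class BlenderFit:
    blender_id: str
    model_ids: tuple[str, ...]
    W: np.ndarray
    train_pred: np.ndarray
    test_pred: np.ndarray
    accuracy: Mapping[str, AccuracyBlock]
    diversity: DiversityStats
    seed: int


def assemble_level0(
    fits: Sequence[LinearFit | EnsembleFit],
) -> Level0Matrix:
    """Column-stack train and test predictions of the given fits."""
    if not fits:
        raise ValueError("no fits supplied")
    n_tr = {len(f.train_pred) for f in fits}
    n_te = {len(f.test_pred) for f in fits}
    if len(n_tr) != 1 or len(n_te) != 1:
        raise ValueError("fits disagree on the split (prediction lengths differ)")
    for f in fits:
        if f.test_pred is None or len(f.test_pred) == 0:
            raise ValueError(f"fit {f.model_id} lacks test predictions")
    return Level0Matrix(
        model_ids=tuple(f.model_id for f in fits),
        train=np.column_stack([f.train_pred for f in fits]),
        test=np.column_stack([f.test_pred for f in fits]),
    )


def fit_blender(
    level0: Level0Matrix,
    y_train,
    y_test,
    blender_id: str = "extra_trees",
    seed: int = 1,
    n_estimators: int = 500,
) -> BlenderFit:
    """Train the level-1 blender and extract model weights W."""
    if level0.train.shape[1] < 2:
        raise ValueError("need at least 2 level-0 models to blend")
    if blender_id == "extra_trees":
        est = ExtraTreesRegressor(n_estimators=n_estimators, random_state=seed)
    elif blender_id == "random_forest":
        est = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    else:
        raise ValueError(
            f"unknown blender_id {blender_id!r}; valid: {BLENDER_IDS}"
        )
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    est.fit(level0.train, y_train)
    W = np.asarray(est.feature_importances_, dtype=float)
    W = W / W.sum()
    train_pred = est.predict(level0.train)
    test_pred = est.predict(level0.test)
    return BlenderFit(
        blender_id=blender_id,
        model_ids=level0.model_ids,
        W=W,
        train_pred=train_pred,
        test_pred=test_pred,
        accuracy={
            "train": accuracy_block(y_train, train_pred),
            "test": accuracy_block(y_test, test_pred),
        },
        diversity=simpson_index(W),
        seed=seed,
    )


def blender_diversity(W) -> DiversityStats:
    """Gini / Simpson / reciprocal-Simpson of a model-weight vector."""
    return simpson_index(W)
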