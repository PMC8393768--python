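"""End-to-end orchestration of the hybrid analysis.

Sequence: impute -> split/scale -> six linear fits + specification tests
-> six tree-ensemble fits -> emulated (L) and actual (M) importances ->
F = (L | M) -> stacking blender -> W -> V = F W -> prior/posterior
weighted arrays -> affinity-propagation clustering and predictive
manifolds -> unsupervised OLS blend -> composite indexes and Kuznets
curves.

``run_analysis`` exposes the sizes that dominate runtime (tree counts,
optional grid search, manifold subset) so small but structurally complete
runs are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import impute as _impute
from .datasets import ENSEMBLE_MODELS, LINEAR_MODELS
from .ensembles import EnsembleFit, fit_ensemble, grid_search_cv
from .importance import (
    ImportanceMatrix,
    ImportanceVector,
    aggregate_importances,
    concat_importance_matrix,
    emulate_importances,
)
from .kuznets import (
    CompositeIndex,
    KuznetsCurve,
    composite_index,
    group_weight_shares,
    kuznets_curves,
)
from .linear import (
    LinearFit,
    SpecTests,
    fit_fixed_effects,
    fit_iv2sls,
    fit_pooled_ols,
    fit_random_effects,
    specification_tests,
)
from .manifolds import (
    MANIFOLD_METHODS,
    ClusterSolution,
    ManifoldPrediction,
    WeightedArray,
    cluster_affinity,
    mds_ecliptic,
    predictive_manifold,
    unsupervised_ols_blend,
    weight_columns,
)
from .preprocess import ScaledSplit, aggregate_by_country, scale_split, split_panel
from .stacking import BlenderFit, assemble_level0, fit_blender
from .synthetic import PanelDataset

__all__ = ["AnalysisResult", "run_analysis"]


@dataclass
class AnalysisResult:
    split: ScaledSplit
    linear_fits: dict[str, LinearFit]
    spec_tests: SpecTests | None
    ensemble_fits: dict[str, EnsembleFit]
    L: pd.DataFrame
    M: pd.DataFrame
    F: ImportanceMatrix
    blender: BlenderFit
    V: ImportanceVector
    prior_array: WeightedArray
    posterior_array: WeightedArray
    country_clusters: dict[str, ClusterSolution]
    manifold_predictions: dict[str, dict[str, ManifoldPrediction]]
    composite_indexes: dict[str, CompositeIndex]
    curves: dict[str, KuznetsCurve]
    group_shares: dict[str, float]
    country_mortality: pd.Series = field(default_factory=pd.Series)

    def mean_manifold_r2(self, tag: str) -> float:
        preds = self.manifold_predictions[tag]
        return float(
            np.mean([p.accuracy.r2 for m, p in preds.items()
                     if m in MANIFOLD_METHODS])
        )


def run_analysis(
    panel: PanelDataset,
    seed: int = 1,
    test_fraction: float = 0.25,
    impute_orders: Mapping[str, int] | None = None,
    ensemble_params: Mapping[str, Mapping] | None = None,
    grids: Mapping[str, Mapping] | None = None,
    cv_folds: int = 5,
    blender_id: str = "extra_trees",
    blender_estimators: int = 500,
    manifold_methods: Sequence[str] = MANIFOLD_METHODS,
    cluster_country_level: bool = True,
) -> AnalysisResult:
    """Run the full hybrid pipeline on a panel.

    ``ensemble_params`` fixes hyperparameters per model id; ``grids``
    triggers a cross-validated grid search instead for the listed models.
    The IV2SLS stage runs only when the panel carries a welfare column.
    """
    if panel.missing_mask.to_numpy().any():
        panel, _ = _impute.impute_panel(panel, order_map=dict(impute_orders or {}))
    train_idx, test_idx = split_panel(panel, test_fraction, seed=seed)
    split = scale_split(panel, train_idx, test_idx)

    linear_fits: dict[str, LinearFit] = {
        "pooled_ols": fit_pooled_ols(split),
        "fee": fit_fixed_effects(split, entity=True, time=False),
        "fte": fit_fixed_effects(split, entity=False, time=True),
        "fete": fit_fixed_effects(split, entity=True, time=True),
        "re": fit_random_effects(split),
    }
    if split.welfare_train is not None:
        linear_fits["iv2sls"] = fit_iv2sls(split)
    spec_tests = None
    if "iv2sls" in linear_fits:
        spec_tests = specification_tests(
            linear_fits["fee"], linear_fits["re"], linear_fits["pooled_ols"],
            split,
        )

    ensemble_fits: dict[str, EnsembleFit] = {}
    for model_id in ENSEMBLE_MODELS:
        params = dict((ensemble_params or {}).get(model_id, {}))
        if grids and model_id in grids:
            best = grid_search_cv(
                model_id, grids[model_id],
                split.X_train.to_numpy(), split.y_train,
                folds=cv_folds, seed=seed,
            )
            params.update(best)
        ensemble_fits[model_id] = fit_ensemble(model_id, split, params, seed=seed)

    features = list(split.feature_names)
    L = pd.DataFrame(
        {
            mid: emulate_importances(
                fit.beta, fit.pvalues, labels=features
            ).weights
            for mid, fit in linear_fits.items()
        },
        index=features,
    )
    M = pd.DataFrame(
        {mid: fit.importances for mid, fit in ensemble_fits.items()},
        index=features,
    )
    F = concat_importance_matrix(L, M)

    level0 = assemble_level0(
        [*linear_fits.values(), *ensemble_fits.values()]
    )
    blender = fit_blender(
        level0, split.y_train, split.y_test,
        blender_id=blender_id, seed=seed, n_estimators=blender_estimators,
    )
    V = aggregate_importances(F, blender.W)

    prior = weight_columns(split.full_scaled_X)
    posterior = weight_columns(split.full_scaled_X, V.weights)

    country_clusters: dict[str, ClusterSolution] = {}
    if cluster_country_level:
        for tag, arr in (("prior", prior), ("posterior", posterior)):
            agg = aggregate_by_country(arr.values, split.entity)
            country_clusters[tag] = cluster_affinity(agg, seed=seed)

    y_full = split.full_scaled_y
    manifold_predictions: dict[str, dict[str, ManifoldPrediction]] = {}
    for tag, arr in (("prior", prior), ("posterior", posterior)):
        preds: dict[str, ManifoldPrediction] = {}
        for method in manifold_methods:
            preds[method] = predictive_manifold(arr, method, y_full, seed=seed)
        if "mds" in manifold_methods:
            preds["mds_ecliptic"] = mds_ecliptic(arr, y_full, seed=seed)
        preds["unsupervised_ols"] = unsupervised_ols_blend(
            [preds[m] for m in preds], y_full
        )
        manifold_predictions[tag] = preds

    composite_indexes = {
        g: composite_index(posterior, g, split.entity) for g in ("economic", "health")
    }
    country_mortality = (
        pd.Series(y_full, index=split.entity).groupby(level=0, sort=False).mean()
    )
    curves = {
        g: kuznets_curves(
            composite_indexes[g].values.to_numpy(),
            country_mortality.loc[composite_indexes[g].values.index].to_numpy(),
        )
        for g in ("economic", "health")
    }

    return AnalysisResult(
        split=split,
        linear_fits=linear_fits,
        spec_tests=spec_tests,
        ensemble_fits=ensemble_fits,
        L=L,
        M=M,
        F=F,
        blender=blender,
        V=V,
        prior_array=prior,
        posterior_array=posterior,
        country_clusters=country_clusters,
        manifold_predictions=manifold_predictions,
        composite_indexes=composite_indexes,
        curves=curves,
        group_shares=group_weight_shares(V),
        country_mortality=country_mortality,
    )
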