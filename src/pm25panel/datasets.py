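"""Feature registry and packaged reference tables.

The analysis covers an EU-27 country-year panel (2008-2018, 297 rows) with
23 named predictors of premature PM2.5 mortality.  Eleven predictors are
primarily economic, twelve primarily environmental/epidemiological; the
split drives the composite Kuznets indexes.

Reference tables from the original EU-27 analysis are bundled as CSV:
feature importances of the six tree-ensemble models, emulated importances
of the six linear models, the linear-model coefficient table (with
significance markers), and the country-level economic index / mortality
pairs.  They serve as fixed inputs for validating the diversity statistics
and the Kuznets curve fits.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: canonical feature order (rows of every importance matrix)
FEATURES: tuple[str, ...] = (
    "expectancy",
    "poverty_threshold",
    "poverty_excluded",
    "poverty_included",
    "emissions",
    "exposure",
    "cardio_incidence",
    "ischemic_incidence",
    "copd_incidence",
    "asthma_incidence",
    "tracheal_incidence",
    "cardio_death",
    "ischemic_death",
    "copd_death",
    "asthma_death",
    "tracheal_death",
    "real_gdp_pc",
    "health_expenditures",
    "environmental_taxes",
    "social_contributions",
    "spending",
    "corruption",
    "gini",
)

ECONOMIC_FEATURES: tuple[str, ...] = (
    "poverty_threshold",
    "poverty_excluded",
    "poverty_included",
    "emissions",
    "real_gdp_pc",
    "health_expenditures",
    "environmental_taxes",
    "social_contributions",
    "spending",
    "corruption",
    "gini",
)

HEALTH_FEATURES: tuple[str, ...] = tuple(
    f for f in FEATURES if f not in ECONOMIC_FEATURES
)

#: feature -> {"economic", "health"}
GROUP_MAP: dict[str, str] = {
    **{f: "economic" for f in ECONOMIC_FEATURES},
    **{f: "health" for f in HEALTH_FEATURES},
}

LINEAR_MODELS: tuple[str, ...] = ("pooled_ols", "fee", "fte", "fete", "re", "iv2sls")
ENSEMBLE_MODELS: tuple[str, ...] = (
    "random_forest",
    "extra_trees",
    "adaboost",
    "gradient_boosting",
    "xgboost",
    "lightgbm",
)

TARGET = "pm25_death"
WELFARE = "welfare_25"
INSTRUMENT = "exposure"


def _read(name: str, index_col=None) -> pd.DataFrame:
    with resources.files("pm25panel.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, index_col=index_col)


def load_ml_importances() -> pd.DataFrame:
    """23 x 6 reference feature importances of the tree-ensemble models."""
    return _read("reference_ml_importances.csv", index_col="variable")


def load_emulated_importances() -> pd.DataFrame:
    """23 x 6 reference emulated importances of the linear models."""
    return _read("reference_emulated_importances.csv", index_col="variable")


def load_linear_coefficients() -> pd.DataFrame:
    """Reference beta coefficients of the six linear models.

    Columns ``<model>`` hold the coefficient, ``<model>_sig`` the printed
    significance marker (``***``/``**``/``*``/``+`` for p < 0.001, 0.01,
    0.05, 0.1; empty when not significant at 0.1).
    """
    return _read("reference_linear_coefficients.csv", index_col="variable")


def load_kuznets_economic() -> pd.DataFrame:
    """Reference 27-country composite economic index and scaled mortality."""
    return _read("reference_kuznets_economic.csv")
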