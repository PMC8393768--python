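"""Shared fixtures: one default synthetic panel and one pipeline run.

The pipeline fixture uses reduced tree counts (100 trees per ensemble,
200 for the blender, no grid search) so the structurally complete run
stays cheap; statistical behaviour is unchanged at these sizes.
"""

import warnings

import pytest

import pm25panel as pp


@pytest.fixture(scope="session")
def default_panel():
    return pp.generate_panel()


@pytest.fixture(scope="session")
def welfare_panel(default_panel):
    return pp.generate_endogenous_welfare(default_panel)


@pytest.fixture(scope="session")
def default_split(welfare_panel):
    train_idx, test_idx = pp.split_panel(welfare_panel)
    return pp.scale_split(welfare_panel, train_idx, test_idx)


@pytest.fixture(scope="session")
def linear_fits(default_split):
    s = default_split
    return {
        "pooled_ols": pp.fit_pooled_ols(s),
        "fee": pp.fit_fixed_effects(s, entity=True, time=False),
        "fte": pp.fit_fixed_effects(s, entity=False, time=True),
        "fete": pp.fit_fixed_effects(s, entity=True, time=True),
        "re": pp.fit_random_effects(s),
        "iv2sls": pp.fit_iv2sls(s),
    }


@pytest.fixture(scope="session")
def pipeline_result(welfare_panel):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pp.run_analysis(
            welfare_panel,
            ensemble_params={
                m: {"n_estimators": 100} for m in pp.ENSEMBLE_MODELS
            },
            blender_estimators=200,
        )
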