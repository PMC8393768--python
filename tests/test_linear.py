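"""Econometric estimators against closed-form and simulation oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.stats.diagnostic as smd

import pm25panel as pp
from pm25panel.linear import _re_transform, durbin_wu_hausman, white_test


def toy_config(k=3, n_entities=6, years=(2008, 2013), beta=None, **kw):
    names = tuple(f"f{i}" for i in range(k))
    return pp.GeneratorConfig(
        n_entities=n_entities,
        year_start=years[0],
        year_end=years[1],
        feature_names=names,
        group_map={n: "health" for n in names},
        beta_true=np.asarray(beta if beta is not None else np.linspace(1, 2, k)),
        year_trend=tuple(np.zeros(years[1] - years[0] + 1)),
        latent_loading=0.0,
        **kw,
    )


def make_split(panel, test_fraction=0.2, seed=1, scale=True):
    tr, te = pp.split_panel(panel, test_fraction, seed=seed)
    return pp.scale_split(panel, tr, te, scale=scale)


class TestPooledOLS:
    def test_exact_linear_target_recovered(self):
        cfg = toy_config(entity_effect_sd=0.0, noise_sd=0.0)
        split = make_split(pp.generate_panel(cfg), scale=False)
        fit = pp.fit_pooled_ols(split)
        np.testing.assert_allclose(fit.beta, cfg.resolved_beta(), atol=1e-8)
        assert fit.accuracy["train"].r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle_on_toy(self):
        cfg = toy_config(k=2, n_entities=5, years=(2008, 2009), noise_sd=0.5)
        split = make_split(pp.generate_panel(cfg), test_fraction=0.2, scale=False)
        fit = pp.fit_pooled_ols(split)
        A = np.column_stack(
            [np.ones(len(split.y_train)), split.X_train.to_numpy()]
        )
        oracle = np.linalg.inv(A.T @ A) @ A.T @ split.y_train
        np.testing.assert_allclose(fit.beta, oracle[1:], atol=1e-10)
        np.testing.assert_allclose(fit.constant, oracle[0], atol=1e-10)

    def test_beta_coefficients_invariant_to_raw_feature_rescaling(
        self, welfare_panel
    ):
        rescaled = welfare_panel.copy()
        rescaled.X["exposure"] = rescaled.X["exposure"] * 1000.0
        f1 = pp.fit_pooled_ols(make_split(welfare_panel, 0.25))
        f2 = pp.fit_pooled_ols(make_split(rescaled, 0.25))
        np.testing.assert_allclose(f1.beta, f2.beta, atol=1e-10)

    def test_rank_deficient_design_names_columns(self, welfare_panel):
        dup = welfare_panel.copy()
        dup.X["gini"] = dup.X["exposure"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            pp.fit_pooled_ols(make_split(dup))


class TestFixedEffects:
    def test_entity_effect_pattern_recovered_at_low_noise(self):
        cfg = toy_config(k=3, n_entities=10, years=(2008, 2018),
                         entity_effect_sd=1.0, noise_sd=0.05)
        panel = pp.generate_panel(cfg)
        split = make_split(panel, test_fraction=0.15, scale=False)
        fit = pp.fit_fixed_effects(split, entity=True)
        truth = panel.truth_effects["alpha"]
        est = fit.entity_effects.reindex(truth.index)
        assert np.corrcoef(est, truth)[0, 1] > 0.99

    def test_zero_entity_effects_match_pooled_ols_within_2se(self):
        cfg = toy_config(k=3, n_entities=10, years=(2008, 2018),
                         entity_effect_sd=0.0, noise_sd=0.3)
        split = make_split(pp.generate_panel(cfg), scale=False)
        ols = pp.fit_pooled_ols(split)
        fee = pp.fit_fixed_effects(split, entity=True)
        se = np.sqrt(np.diag(ols.cov))
        assert np.all(np.abs(fee.beta - ols.beta) < 2 * se)

    def test_fete_reports_27_entity_and_11_year_effects(self, linear_fits):
        fete = linear_fits["fete"]
        assert len(fete.entity_effects) == 27
        assert len(fete.time_effects) == 11
        # recentred time effects have mean zero
        assert abs(fete.time_effects.mean()) < 1e-10

    def test_fee_slopes_equal_within_estimator(self, default_split):
        # LSDV slopes == OLS on entity-demeaned data
        fee = pp.fit_fixed_effects(default_split, entity=True)
        X = default_split.X_train.to_numpy()
        y = np.asarray(default_split.y_train)
        ents = pd.Series(default_split.entity_train)
        Xd, yd = X.copy(), y.copy()
        for _, idx in ents.groupby(ents).groups.items():
            idx = np.asarray(idx)
            Xd[idx] -= Xd[idx].mean(axis=0)
            yd[idx] -= yd[idx].mean()
        beta_within, *_ = np.linalg.lstsq(Xd, yd, rcond=None)
        np.testing.assert_allclose(fee.beta, beta_within, atol=1e-8)

    def test_no_margin_selected_rejected(self, default_split):
        with pytest.raises(ValueError):
            pp.fit_fixed_effects(default_split, entity=False, time=False)

    def test_single_row_entity_rejected(self):
        cfg = toy_config(k=2, n_entities=4, years=(2008, 2011))
        panel = pp.generate_panel(cfg)
        # test split leaving entity 0 with one train row
        rows = np.nonzero(panel.entity == panel.entities[0])[0]
        te = rows[1:]
        tr = np.setdiff1d(np.arange(panel.n_rows), te)
        split = pp.scale_split(panel, tr, te)
        with pytest.raises(ValueError, match="single train row"):
            pp.fit_fixed_effects(split, entity=True)


class TestRandomEffects:
    def test_zero_entity_variance_collapses_to_pooled_ols(self):
        cfg = toy_config(k=3, n_entities=10, years=(2008, 2018),
                         entity_effect_sd=0.0, noise_sd=0.3)
        split = make_split(pp.generate_panel(cfg), scale=False)
        ols = pp.fit_pooled_ols(split)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # variance clipping may or may not fire
            re = pp.fit_random_effects(split)
        se = np.sqrt(np.diag(ols.cov))
        assert np.all(np.abs(re.beta - ols.beta) < 2 * se)

    def test_quasi_demeaning_equals_dense_gls_oracle(self):
        rng = np.random.default_rng(5)
        entities = np.repeat(["a", "b", "c"], 4)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        s2e, s2a = 1.3, 0.7
        design, yt = _re_transform(X, y, entities, s2e, s2a)
        beta_qd = np.linalg.lstsq(design, yt, rcond=None)[0]
        # dense GLS with the block covariance Omega
        Omega = np.zeros((12, 12))
        for g in range(3):
            sl = slice(4 * g, 4 * g + 4)
            Omega[sl, sl] = s2a
        Omega[np.diag_indices(12)] += s2e
        Z = np.column_stack([np.ones(12), X])
        Oi = np.linalg.inv(Omega)
        beta_gls = np.linalg.solve(Z.T @ Oi @ Z, Z.T @ Oi @ y)
        np.testing.assert_allclose(beta_qd, beta_gls, atol=1e-8)

    def test_reports_a_constant(self, linear_fits):
        assert isinstance(linear_fits["re"].constant, float)
        assert np.isfinite(linear_fits["re"].constant)


class TestIV2SLS:
    def test_perfect_instrument_limit_equals_ols(self):
        cfg = toy_config(k=3, n_entities=8, years=(2008, 2015), noise_sd=0.3)
        panel = pp.generate_panel(cfg)
        rng = np.random.default_rng(2)
        welfare = 0.5 * panel.y + rng.normal(0, 0.5, panel.n_rows)
        panel.welfare = welfare
        panel.X["f2"] = welfare  # instrument column identical to endog
        panel.instrument_name = "f2"
        split = make_split(panel, scale=False)
        fit = pp.fit_iv2sls(split)
        A = np.column_stack([
            np.ones(len(split.y_train)),
            split.X_train[["f0", "f1"]].to_numpy(),
            split.welfare_train,
        ])
        ols = np.linalg.lstsq(A, split.y_train, rcond=None)[0]
        # welfare coefficient is reported under the instrument's label
        assert fit.beta[list(split.feature_names).index("f2")] == pytest.approx(
            ols[-1], abs=1e-8
        )

    def test_matches_two_stage_by_hand_oracle(self, default_split):
        fit = pp.fit_iv2sls(default_split)
        s = default_split
        exog = [f for f in s.feature_names if f != s.instrument_name]
        n = len(s.y_train)
        Z = np.column_stack([
            np.ones(n), s.X_train[exog].to_numpy(),
            s.X_train[s.instrument_name].to_numpy(),
        ])
        w_hat = Z @ np.linalg.lstsq(Z, s.welfare_train, rcond=None)[0]
        A = np.column_stack([np.ones(n), s.X_train[exog].to_numpy(), w_hat])
        oracle = np.linalg.lstsq(A, s.y_train, rcond=None)[0]
        got = np.concatenate([[fit.constant], fit.beta[
            [list(s.feature_names).index(f) for f in exog]
        ], [fit.beta[list(s.feature_names).index(s.instrument_name)]]])
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_r2_not_above_ols_on_same_structural_design(self, default_split):
        fit = pp.fit_iv2sls(default_split)
        s = default_split
        exog = [f for f in s.feature_names if f != s.instrument_name]
        A = np.column_stack([
            np.ones(len(s.y_train)), s.X_train[exog].to_numpy(),
            s.welfare_train,
        ])
        res = sm.OLS(s.y_train, A).fit()
        assert fit.accuracy["train"].r2 <= res.rsquared + 1e-12

    def test_missing_welfare_rejected(self, default_panel):
        split = make_split(default_panel)
        with pytest.raises(ValueError, match="welfare"):
            pp.fit_iv2sls(split)


class TestSpecificationTests:
    def test_hausman_statistic_non_negative(self, linear_fits, default_split):
        tests = pp.specification_tests(
            linear_fits["fee"], linear_fits["re"],
            linear_fits["pooled_ols"], default_split,
        )
        stat, df, p = tests.hausman
        assert stat >= 0.0
        assert df == 23
        assert 0.0 <= p <= 1.0

    def test_endogenous_welfare_detected(self, default_split):
        (durbin, p_d), (wu, p_w) = durbin_wu_hausman(default_split)
        assert durbin > 0 and wu > 0
        assert p_d < 0.01 and p_w < 0.01

    def test_white_matches_statsmodels_on_small_case(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(120, 3))
        beta = np.array([1.0, -0.5, 0.2])
        y = X @ beta + rng.normal(size=120)
        Xc = sm.add_constant(X)
        resid = y - Xc @ np.linalg.lstsq(Xc, y, rcond=None)[0]
        lm, df, p = white_test(resid, X)
        lm_sm, p_sm, _, _ = smd.het_white(resid, Xc)
        assert lm == pytest.approx(lm_sm, abs=1e-6)
        assert p == pytest.approx(p_sm, abs=1e-8)


class TestAccuracyBlock:
    def test_perfect_prediction(self):
        block = pp.accuracy_block([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (block.rmse, block.r2, block.mbe, block.wioa) == (0, 1, 0, 1)

    def test_constant_shift(self):
        block = pp.accuracy_block([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert block.mbe == pytest.approx(0.5)
        assert block.rmse == pytest.approx(0.5)

    def test_three_point_wioa_by_hand(self):
        obs = np.array([0.0, 1.0, 2.0])
        pred = np.array([0.5, 1.0, 1.5])
        block = pp.accuracy_block(obs, pred)
        assert block.wioa == pytest.approx(1.0 - 0.5 / 4.5)
        assert block.r2 == pytest.approx(0.75)
        assert block.rmse == pytest.approx(np.sqrt(0.5 / 3))

    def test_constant_obs_flagged(self):
        with pytest.warns(UserWarning, match="r2 undefined"):
            block = pp.accuracy_block([1.0, 1.0, 1.0], [1.0, 2.0, 1.0])
        assert np.isnan(block.r2)


def test_coefficient_table_has_stars(linear_fits):
    table = pp.coefficient_table(linear_fits)
    assert table.shape == (23, 12)
    stars = set(table["pooled_ols_sig"].unique())
    assert stars <= {"", "+", "*", "**", "***"}
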