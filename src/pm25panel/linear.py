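"""Panel econometrics: pooled OLS, fixed/random effects, IV2SLS.

All six estimators operate on the standardized train partition, so their
coefficients are beta coefficients.  Fixed effects are estimated by LSDV
(dummy variables) so entity and time effects are directly reportable;
slopes coincide with the within-transformation estimator.  Random effects
use feasible GLS via quasi-demeaning with Swamy-Arora-style variance
components.  IV2SLS instruments the endogenous welfare variable with
PM2.5 exposure; the instrument is excluded from the structural equation
and the instrumented coefficient is reported under the instrument's label.

Specification tests: Hausman (FE vs RE contrast with a pseudo-inverse
guarded to be non-negative), Durbin and Wu-Hausman residual-augmentation
exogeneity tests, and White's LM heteroskedasticity test.

Model accuracy is summarized by a four-statistic block — RMSE, r², mean
bias error and Willmott's index of agreement — always reported separately
for the train and test partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .datasets import WELFARE
from .preprocess import ScaledSplit

__all__ = [
    "AccuracyBlock",
    "LinearFit",
    "SpecTests",
    "accuracy_block",
    "fit_pooled_ols",
    "fit_fixed_effects",
    "fit_random_effects",
    "fit_iv2sls",
    "specification_tests",
    "significance_stars",
    "coefficient_table",
]


@dataclass(frozen=True)
class AccuracyBlock:
    rmse: float
    r2: float
    mbe: float
    wioa: float


def accuracy_block(obs, pred) -> AccuracyBlock:
    """RMSE, r², mean bias error and Willmott's index of agreement."""
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("obs and pred must be equal-length vectors, n >= 2")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(p))):
        raise ValueError("obs and pred must be finite")
    err = p - o
    sse = float(np.sum(err**2))
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        warnings.warn("constant observation vector: r2 undefined", stacklevel=2)
        r2 = np.nan
    else:
        r2 = 1.0 - sse / sst
    denom = float(np.sum((np.abs(p - o.mean()) + np.abs(o - o.mean())) ** 2))
    wioa = 1.0 - sse / denom if denom > 0 else np.nan
    return AccuracyBlock(
        rmse=float(np.sqrt(np.mean(err**2))),
        r2=r2,
        mbe=float(np.mean(err)),
        wioa=wioa,
    )


@dataclass
class LinearFit:
    """A fitted linear panel model with report-ready pieces."""

    model_id: str
    feature_names: tuple[str, ...]
    beta: np.ndarray
    pvalues: np.ndarray
    constant: float
    cov: np.ndarray  # covariance of the feature slopes
    residual_variance: float
    train_pred: np.ndarray
    test_pred: np.ndarray
    accuracy: Mapping[str, AccuracyBlock]
    entity_effects: pd.Series | None = None
    time_effects: pd.Series | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.feature_names)
        if len(self.beta) != k or len(self.pvalues) != k:
            raise ValueError("beta and pvalues must match feature_names")
        if np.any((self.pvalues < 0) | (self.pvalues > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        if not (
            np.all(np.isfinite(self.train_pred))
            and np.all(np.isfinite(self.test_pred))
        ):
            raise ValueError("predictions must be finite")

    def to_dict(self) -> dict:
        out = {
            "model_id": self.model_id,
            "beta": dict(zip(self.feature_names, map(float, self.beta))),
            "pvalues": dict(zip(self.feature_names, map(float, self.pvalues))),
            "constant": self.constant,
            "residual_variance": self.residual_variance,
            "accuracy": {
                part: vars(block) for part, block in self.accuracy.items()
            },
        }
        if self.entity_effects is not None:
            out["entity_effects"] = self.entity_effects.to_dict()
        if self.time_effects is not None:
            out["time_effects"] = self.time_effects.to_dict()
        return out


@dataclass(frozen=True)
class SpecTests:
    hausman: tuple[float, int, float]  # (chi2, df, p)
    durbin: tuple[float, float]  # (stat, p)
    wu_hausman: tuple[float, float]  # (F, p)
    white: tuple[float, int, float]  # (LM, df, p)


def _check_full_rank(X: pd.DataFrame) -> None:
    A = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        _, _, piv = scipy.linalg.qr(A, pivoting=True)
        dropped = sorted(piv[rank:])
        names = ["const"] + list(X.columns)
        raise ValueError(
            f"rank-deficient design; collinear columns: "
            f"{[names[i] for i in dropped]}"
        )


def fit_pooled_ols(split: ScaledSplit) -> LinearFit:
    """Baseline pooled OLS with an intercept on the scaled train data."""
    if len(split.train_idx) <= len(split.feature_names) + 1:
        raise ValueError("too few train rows for a 23-feature regression")
    _check_full_rank(split.X_train)
    X = sm.add_constant(split.X_train.to_numpy(dtype=float))
    res = sm.OLS(split.y_train, X).fit()
    test_pred = res.params[0] + split.X_test.to_numpy() @ res.params[1:]
    return LinearFit(
        model_id="pooled_ols",
        feature_names=split.feature_names,
        beta=res.params[1:],
        pvalues=res.pvalues[1:],
        constant=float(res.params[0]),
        cov=res.cov_params()[1:, 1:],
        residual_variance=float(res.mse_resid),
        train_pred=res.fittedvalues,
        test_pred=test_pred,
        accuracy={
            "train": accuracy_block(split.y_train, res.fittedvalues),
            "test": accuracy_block(split.y_test, test_pred),
        },
    )


def _dummies(labels: np.ndarray, drop_first: bool = False) -> pd.DataFrame:
    d = pd.get_dummies(pd.Series(labels).astype(str), drop_first=drop_first)
    return d.astype(float)


def fit_fixed_effects(
    split: ScaledSplit, entity: bool = True, time: bool = False
) -> LinearFit:
    """LSDV fixed-effects estimation (entity, time, or both).

    Entity dummies enter without an intercept so every entity effect is
    reportable.  With both margins, one reference year is absorbed and the
    recovered time effects are recentred to mean zero, the shift being
    folded into the entity effects; fitted values are unaffected by that
    reparametrization.
    """
    if not (entity or time):
        raise ValueError("at least one of entity/time must be set")
    ent_tr = split.entity_train.astype(str)
    yr_tr = split.year_train.astype(str)
    if entity:
        counts = pd.Series(ent_tr).value_counts()
        if (counts < 2).any():
            raise ValueError(
                f"entities with a single train row: "
                f"{counts.index[counts < 2].tolist()}"
            )
    if time:
        counts = pd.Series(yr_tr).value_counts()
        if (counts < 2).any():
            raise ValueError(
                f"years with a single train row: "
                f"{counts.index[counts < 2].tolist()}"
            )

    k = len(split.feature_names)
    blocks = [split.X_train.to_numpy(dtype=float)]
    names: list[str] = list(split.feature_names)
    if entity and time:
        ent_d = _dummies(ent_tr)
        yr_d = _dummies(yr_tr, drop_first=True)
        ref_year = sorted(set(yr_tr) - set(yr_d.columns))[0]
        blocks += [ent_d.to_numpy(), yr_d.to_numpy()]
        names += [f"ent_{c}" for c in ent_d.columns]
        names += [f"yr_{c}" for c in yr_d.columns]
        model_id = "fete"
    elif entity:
        ent_d = _dummies(ent_tr)
        blocks.append(ent_d.to_numpy())
        names += [f"ent_{c}" for c in ent_d.columns]
        model_id = "fee"
    else:
        yr_d = _dummies(yr_tr)
        blocks.append(yr_d.to_numpy())
        names += [f"yr_{c}" for c in yr_d.columns]
        model_id = "fte"

    design = np.column_stack(blocks)
    res = sm.OLS(split.y_train, design).fit()

    entity_effects: pd.Series | None = None
    time_effects: pd.Series | None = None
    if entity:
        entity_effects = pd.Series(
            {c: res.params[names.index(f"ent_{c}")] for c in ent_d.columns}
        )
    if time and entity:
        gamma = pd.Series(
            {c: res.params[names.index(f"yr_{c}")] for c in yr_d.columns}
        )
        gamma[ref_year] = 0.0
        gamma = gamma.sort_index()
        shift = gamma.mean()
        time_effects = gamma - shift
        entity_effects = entity_effects + shift
    elif time:
        time_effects = pd.Series(
            {c: res.params[names.index(f"yr_{c}")] for c in yr_d.columns}
        ).sort_index()

    def predict(X: pd.DataFrame, ents: np.ndarray, yrs: np.ndarray) -> np.ndarray:
        out = X.to_numpy(dtype=float) @ res.params[:k]
        if entity_effects is not None:
            out = out + np.array(
                [entity_effects.get(e, 0.0) for e in ents.astype(str)]
            )
        if time_effects is not None:
            out = out + np.array(
                [time_effects.get(y, 0.0) for y in yrs.astype(str)]
            )
        return out

    test_pred = predict(split.X_test, split.entity_test, split.year_test)
    return LinearFit(
        model_id=model_id,
        feature_names=split.feature_names,
        beta=res.params[:k],
        pvalues=res.pvalues[:k],
        constant=0.0,
        cov=res.cov_params()[:k, :k],
        residual_variance=float(res.mse_resid),
        train_pred=res.fittedvalues,
        test_pred=test_pred,
        accuracy={
            "train": accuracy_block(split.y_train, res.fittedvalues),
            "test": accuracy_block(split.y_test, test_pred),
        },
        entity_effects=entity_effects,
        time_effects=time_effects,
    )


def _re_transform(X, y, entities, sigma2_e, sigma2_a):
    """Quasi-demean rows; OLS on the result equals GLS with these components."""
    ent = pd.Series(np.asarray(entities).astype(str))
    Xt = np.asarray(X, dtype=float).copy()
    yt = np.asarray(y, dtype=float).copy()
    const = np.ones(len(yt))
    for e, idx in ent.groupby(ent).groups.items():
        idx = np.asarray(idx)
        T_i = len(idx)
        theta = 1.0 - np.sqrt(sigma2_e / (sigma2_e + T_i * sigma2_a))
        Xt[idx] -= theta * Xt[idx].mean(axis=0)
        yt[idx] -= theta * yt[idx].mean()
        const[idx] -= theta
    return np.column_stack([const, Xt]), yt


def fit_random_effects(split: ScaledSplit) -> LinearFit:
    """Feasible GLS random effects via quasi-demeaning.

    Variance components follow the Swamy-Arora idea: the idiosyncratic
    variance comes from the within (entity-demeaned) regression, the
    entity variance from the between regression of entity means, clipped
    at zero with a warning if the difference turns negative.
    """
    X = split.X_train.to_numpy(dtype=float)
    y = np.asarray(split.y_train, dtype=float)
    ents = split.entity_train.astype(str)
    k = X.shape[1]
    ent_series = pd.Series(ents)
    groups = ent_series.groupby(ent_series).groups
    n_ent = len(groups)
    if len(y) < 2 * n_ent:
        warnings.warn("fewer than 2 rows per entity on average", stacklevel=2)

    # within residual variance
    Xw, yw = X.copy(), y.copy()
    for idx in groups.values():
        idx = np.asarray(idx)
        Xw[idx] -= Xw[idx].mean(axis=0)
        yw[idx] -= yw[idx].mean()
    beta_w, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    ssr_w = float(np.sum((yw - Xw @ beta_w) ** 2))
    df_w = len(y) - n_ent - k
    if df_w <= 0:
        raise ValueError("not enough rows to estimate the within variance")
    sigma2_e = ssr_w / df_w

    # between regression on entity means
    Xb = np.vstack([X[np.asarray(idx)].mean(axis=0) for idx in groups.values()])
    yb = np.array([y[np.asarray(idx)].mean() for idx in groups.values()])
    T_bar = len(y) / n_ent
    df_b = n_ent - k - 1
    if df_b > 0:
        Zb = np.column_stack([np.ones(n_ent), Xb])
        bb, *_ = np.linalg.lstsq(Zb, yb, rcond=None)
        sigma2_b = float(np.sum((yb - Zb @ bb) ** 2)) / df_b
    else:
        sigma2_b = float(np.var(yb, ddof=1))
    sigma2_a = sigma2_b - sigma2_e / T_bar
    if sigma2_a < 0.0:
        warnings.warn(
            "negative entity variance component clipped to 0", stacklevel=2
        )
        sigma2_a = 0.0

    design, yt = _re_transform(X, y, ents, sigma2_e, sigma2_a)
    res = sm.OLS(yt, design).fit()
    beta = res.params[1:]
    const = float(res.params[0])
    train_pred = const + X @ beta
    test_pred = const + split.X_test.to_numpy(dtype=float) @ beta
    return LinearFit(
        model_id="re",
        feature_names=split.feature_names,
        beta=beta,
        pvalues=res.pvalues[1:],
        constant=const,
        cov=res.cov_params()[1:, 1:],
        residual_variance=sigma2_e,
        train_pred=train_pred,
        test_pred=test_pred,
        accuracy={
            "train": accuracy_block(split.y_train, train_pred),
            "test": accuracy_block(split.y_test, test_pred),
        },
        extras={"sigma2_entity": sigma2_a, "sigma2_idiosyncratic": sigma2_e},
    )


def _iv_pieces(split: ScaledSplit):
    if split.welfare_train is None:
        raise ValueError(f"panel has no {WELFARE} column; generate it first")
    instr = split.instrument_name
    exog_names = [f for f in split.feature_names if f != instr]
    Xe_tr = split.X_train[exog_names].to_numpy(dtype=float)
    Xe_te = split.X_test[exog_names].to_numpy(dtype=float)
    z_tr = split.X_train[instr].to_numpy(dtype=float)
    return exog_names, Xe_tr, Xe_te, z_tr


def fit_iv2sls(split: ScaledSplit) -> LinearFit:
    """Two-stage least squares with exposure instrumenting welfare.

    Structural equation: the 22 exogenous features plus the instrumented
    endogenous welfare variable (the instrument itself is excluded).  The
    welfare coefficient is reported under the instrument's label so the
    coefficient vector stays aligned with the 23 canonical features.
    """
    exog_names, Xe_tr, Xe_te, z_tr = _iv_pieces(split)
    w_tr = np.asarray(split.welfare_train, dtype=float)
    n = len(w_tr)

    Z = np.column_stack([np.ones(n), Xe_tr, z_tr])  # instruments
    coef_fs, *_ = np.linalg.lstsq(Z, w_tr, rcond=None)
    w_hat = Z @ coef_fs
    sst_w = float(np.sum((w_tr - w_tr.mean()) ** 2))
    fs_r2 = 1.0 - float(np.sum((w_tr - w_hat) ** 2)) / sst_w
    if fs_r2 < 1e-6:
        raise ValueError(f"weak instrument: first-stage r2 = {fs_r2:.2e}")

    X_struct = np.column_stack([np.ones(n), Xe_tr, w_tr])
    X_hat = np.column_stack([np.ones(n), Xe_tr, w_hat])
    y = np.asarray(split.y_train, dtype=float)
    beta = np.linalg.solve(X_hat.T @ X_hat, X_hat.T @ y)
    resid = y - X_struct @ beta  # residuals use the actual endogenous values
    k = X_struct.shape[1]
    sigma2 = float(resid @ resid) / (n - k)
    cov = sigma2 * np.linalg.inv(X_hat.T @ X_hat)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tstat), df=n - k)

    # reorder into canonical feature order, welfare under the instrument slot
    order = {name: i + 1 for i, name in enumerate(exog_names)}
    order[split.instrument_name] = len(exog_names) + 1  # welfare column
    idx = [order[f] for f in split.feature_names]
    beta_c = beta[idx]
    pvals_c = pvals[idx]
    cov_c = cov[np.ix_(idx, idx)]

    train_pred = X_struct @ beta
    w_te = np.asarray(split.welfare_test, dtype=float)
    test_pred = (
        beta[0] + Xe_te @ beta[1:-1] + w_te * beta[-1]
    )
    return LinearFit(
        model_id="iv2sls",
        feature_names=split.feature_names,
        beta=beta_c,
        pvalues=pvals_c,
        constant=float(beta[0]),
        cov=cov_c,
        residual_variance=sigma2,
        train_pred=train_pred,
        test_pred=test_pred,
        accuracy={
            "train": accuracy_block(split.y_train, train_pred),
            "test": accuracy_block(split.y_test, test_pred),
        },
        extras={"first_stage_r2": fs_r2, "endogenous": WELFARE},
    )


def hausman_test(fe_fit: LinearFit, re_fit: LinearFit) -> tuple[float, int, float]:
    """FE-vs-RE contrast with a positive-part pseudo-inverse."""
    if fe_fit.feature_names != re_fit.feature_names:
        raise ValueError("fits must share the same feature design")
    d = fe_fit.beta - re_fit.beta
    V = fe_fit.cov - re_fit.cov
    V = (V + V.T) / 2.0
    # Moore-Penrose inverse; the difference matrix need not be positive
    # definite in finite samples, so the quadratic form is floored at 0
    stat = max(float(d @ np.linalg.pinv(V) @ d), 0.0)
    df = len(d)
    return stat, df, float(scipy.stats.chi2.sf(stat, df))


def durbin_wu_hausman(split: ScaledSplit) -> tuple[tuple[float, float], tuple[float, float]]:
    """Durbin χ² and Wu-Hausman F exogeneity tests for the welfare variable."""
    exog_names, Xe_tr, _, z_tr = _iv_pieces(split)
    w = np.asarray(split.welfare_train, dtype=float)
    y = np.asarray(split.y_train, dtype=float)
    n = len(y)
    Z = np.column_stack([np.ones(n), Xe_tr, z_tr])
    v = w - Z @ np.linalg.lstsq(Z, w, rcond=None)[0]

    X_r = np.column_stack([np.ones(n), Xe_tr, w])
    X_u = np.column_stack([X_r, v])

    def ssr(A):
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        r = y - A @ coef
        return float(r @ r)

    ssr_r, ssr_u = ssr(X_r), ssr(X_u)
    durbin = n * (ssr_r - ssr_u) / ssr_r
    p_durbin = float(scipy.stats.chi2.sf(durbin, 1))
    df_u = n - X_u.shape[1]
    wu = (ssr_r - ssr_u) / (ssr_u / df_u)
    p_wu = float(scipy.stats.f.sf(wu, 1, df_u))
    return (float(durbin), p_durbin), (float(wu), p_wu)


def white_test(residuals, X) -> tuple[float, int, float]:
    """White LM test: squared residuals on regressors, squares, cross terms."""
    X = np.asarray(X, dtype=float)
    e2 = np.asarray(residuals, dtype=float) ** 2
    n, k = X.shape
    cols = [np.ones(n), *(X[:, j] for j in range(k))]
    cols += [X[:, i] * X[:, j] for i in range(k) for j in range(i, k)]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, e2, rcond=None)
    resid = e2 - A @ coef
    sst = float(np.sum((e2 - e2.mean()) ** 2))
    if sst == 0.0:
        return 0.0, 0, 1.0
    r2 = 1.0 - float(resid @ resid) / sst
    df = np.linalg.matrix_rank(A) - 1
    lm = n * r2
    return float(lm), int(df), float(scipy.stats.chi2.sf(lm, df))


def specification_tests(
    fee_fit: LinearFit,
    re_fit: LinearFit,
    ols_fit: LinearFit,
    split: ScaledSplit,
) -> SpecTests:
    """Hausman, Durbin, Wu-Hausman and White tests on the train partition."""
    hausman = hausman_test(fee_fit, re_fit)
    durbin, wu = durbin_wu_hausman(split)
    resid = np.asarray(split.y_train, dtype=float) - ols_fit.train_pred
    white = white_test(resid, split.X_train.to_numpy(dtype=float))
    return SpecTests(hausman=hausman, durbin=durbin, wu_hausman=wu, white=white)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


def coefficient_table(fits: Mapping[str, LinearFit]) -> pd.DataFrame:
    """Report-style table of beta coefficients with significance stars."""
    out = {}
    for model_id, fit in fits.items():
        out[model_id] = pd.Series(fit.beta, index=list(fit.feature_names))
        out[f"{model_id}_sig"] = pd.Series(
            [significance_stars(p) for p in fit.pvalues],
            index=list(fit.feature_names),
        )
    return pd.DataFrame(out)
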