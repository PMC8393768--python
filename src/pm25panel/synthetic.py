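"""Synthetic EU-27-style mortality panels.

The real country-year panel behind the analysis (27 entities, 2008-2018,
23 predictors of premature PM2.5 mortality) is not publicly deposited, so
every downstream stage is exercised on generated panels that share its
statistical structure:

* two latent factors (economic, health) with per-feature loadings, so that
  features intercorrelate within their group and PCA composite indexes are
  recoverable;
* a linear outcome ``y = X beta + alpha_i + gamma_t + eps`` with entity
  effects, a year trend whose default sign pattern is positive 2008-2011
  and negative afterwards, and i.i.d. Gaussian noise;
* an optional endogenous welfare variable constructed as a linear
  combination of the target, the instrument column and fresh noise, with
  the two weights solved analytically to hit requested correlations
  (defaults 0.940138 with the target and 0.769063 with exposure);
* missingness masks drawn completely at random per feature (the reference
  pattern: 54 exposure cells, 2 copd_death cells, 3 tracheal_death cells).

Default effect sizes are the reference pooled-OLS beta coefficients, so
synthetic inference tests are sign-consistent with the published fits.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .datasets import FEATURES, GROUP_MAP, INSTRUMENT, TARGET, WELFARE

__all__ = [
    "GeneratorConfig",
    "PanelDataset",
    "generate_panel",
    "generate_endogenous_welfare",
    "inject_missingness",
    "read_panel_csv",
]

#: reference FETE time effects, 2008..2018 (positive through 2011, then negative)
DEFAULT_YEAR_TREND: tuple[float, ...] = (
    0.399014, 0.392836, 0.421352, 0.426721, -0.052770, -0.227695,
    -0.193217, -0.328103, -0.260225, -0.338013, -0.298708,
)


def _default_beta() -> np.ndarray:
    """Reference pooled-OLS beta coefficients, in canonical feature order."""
    table = datasets.load_linear_coefficients()
    return table.loc[list(FEATURES), "pooled_ols"].to_numpy(dtype=float)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic panel generator.

    ``latent_loading`` is the loading of each feature on its group factor
    (economic or health); ``sqrt(1 - loading^2)`` of the variance is
    idiosyncratic, so features are generated with unit variance.
    """

    n_entities: int = 27
    year_start: int = 2008
    year_end: int = 2018
    feature_names: tuple[str, ...] = FEATURES
    group_map: Mapping[str, str] = field(default_factory=lambda: dict(GROUP_MAP))
    beta_true: np.ndarray | None = None
    entity_effect_sd: float = 0.4
    year_trend: tuple[float, ...] | None = None
    noise_sd: float = 0.2
    latent_loading: float | Mapping[str, float] = 0.8
    #: share of each latent factor's variance that is entity-level (vs per-row)
    latent_entity_share: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_entities < 2:
            raise ValueError("need at least 2 entities")
        if self.n_years < 2:
            raise ValueError("need at least 2 years")
        beta = self.resolved_beta()
        if len(beta) != len(self.feature_names):
            raise ValueError(
                f"beta_true must have {len(self.feature_names)} entries"
            )
        if not np.all(np.isfinite(beta)):
            raise ValueError("beta_true must be finite")
        if not (np.isfinite(self.noise_sd) and self.noise_sd >= 0):
            raise ValueError("noise_sd must be finite and >= 0")
        if not (np.isfinite(self.entity_effect_sd) and self.entity_effect_sd >= 0):
            raise ValueError("entity_effect_sd must be finite and >= 0")
        trend = self.resolved_year_trend()
        if len(trend) != self.n_years:
            raise ValueError(
                f"year_trend must have {self.n_years} entries, got {len(trend)}"
            )
        if not np.all(np.isfinite(trend)):
            raise ValueError("year_trend must be finite")
        for name in self.feature_names:
            lam = self.loading_of(name)
            if not (np.isfinite(lam) and 0.0 <= lam <= 1.0):
                raise ValueError(f"latent loading for {name} must be in [0, 1]")
        if not 0.0 <= self.latent_entity_share <= 1.0:
            raise ValueError("latent_entity_share must be in [0, 1]")

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def resolved_beta(self) -> np.ndarray:
        if self.beta_true is None:
            if self.feature_names != FEATURES:
                raise ValueError(
                    "beta_true must be given explicitly for custom features"
                )
            return _default_beta()
        return np.asarray(self.beta_true, dtype=float)

    def resolved_year_trend(self) -> np.ndarray:
        if self.year_trend is None:
            if self.n_years == len(DEFAULT_YEAR_TREND):
                return np.asarray(DEFAULT_YEAR_TREND)
            return np.zeros(self.n_years)
        return np.asarray(self.year_trend, dtype=float)

    def loading_of(self, feature: str) -> float:
        if isinstance(self.latent_loading, Mapping):
            return float(self.latent_loading.get(feature, 0.8))
        return float(self.latent_loading)

    def to_json(self) -> str:
        """Serialize the resolved configuration (for an exact rerun)."""
        import json

        return json.dumps(
            {
                "n_entities": self.n_entities,
                "year_start": self.year_start,
                "year_end": self.year_end,
                "feature_names": list(self.feature_names),
                "group_map": dict(self.group_map),
                "beta_true": self.resolved_beta().tolist(),
                "entity_effect_sd": self.entity_effect_sd,
                "year_trend": self.resolved_year_trend().tolist(),
                "noise_sd": self.noise_sd,
                "latent_loading": (
                    dict(self.latent_loading)
                    if isinstance(self.latent_loading, Mapping)
                    else self.latent_loading
                ),
                "latent_entity_share": self.latent_entity_share,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, blob: str) -> "GeneratorConfig":
        import json

        data = json.loads(blob)
        data["feature_names"] = tuple(data["feature_names"])
        data["beta_true"] = np.asarray(data["beta_true"])
        data["year_trend"] = tuple(data["year_trend"])
        return cls(**data)


@dataclass
class PanelDataset:
    """A long-format entity-year panel with one row per (entity, year)."""

    entity: np.ndarray
    year: np.ndarray
    X: pd.DataFrame
    y: np.ndarray
    missing_mask: pd.DataFrame
    welfare: np.ndarray | None = None
    instrument_name: str = INSTRUMENT
    truth: GeneratorConfig | None = None
    #: realized entity effects / year trend of the generating draw
    truth_effects: dict | None = None

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.entity) == len(self.year) == len(self.X) == n):
            raise ValueError("entity, year, X and y must have equal length")
        if self.missing_mask.shape != self.X.shape:
            raise ValueError("missing_mask must align with X")
        pairs = pd.MultiIndex.from_arrays([self.entity, self.year])
        if pairs.has_duplicates:
            raise ValueError("every (entity, year) pair must appear exactly once")

    @property
    def n_rows(self) -> int:
        return len(self.y)

    @property
    def entities(self) -> np.ndarray:
        """Unique entity labels in first-appearance order."""
        return pd.unique(self.entity)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)

    def copy(self) -> "PanelDataset":
        return dataclasses.replace(
            self,
            entity=self.entity.copy(),
            year=self.year.copy(),
            X=self.X.copy(),
            y=self.y.copy(),
            missing_mask=self.missing_mask.copy(),
            welfare=None if self.welfare is None else self.welfare.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: entity, year, features, target, welfare."""
        out = pd.DataFrame({"entity": self.entity, "year": self.year})
        out = pd.concat([out, self.X.reset_index(drop=True)], axis=1)
        out[TARGET] = self.y
        if self.welfare is not None:
            out[WELFARE] = self.welfare
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_panel_csv(path, instrument_name: str = INSTRUMENT) -> PanelDataset:
    """Load a long-format panel CSV; empty feature cells become masked."""
    frame = pd.read_csv(path)
    feature_cols = [
        c for c in frame.columns if c not in ("entity", "year", TARGET, WELFARE)
    ]
    X = frame[feature_cols].astype(float)
    return PanelDataset(
        entity=frame["entity"].to_numpy(),
        year=frame["year"].to_numpy(dtype=int),
        X=X,
        y=frame[TARGET].to_numpy(dtype=float),
        missing_mask=X.isna(),
        welfare=frame[WELFARE].to_numpy(dtype=float) if WELFARE in frame else None,
        instrument_name=instrument_name,
    )


def generate_panel(config: GeneratorConfig | None = None) -> PanelDataset:
    """Draw a panel from the latent-factor generating process.

    Deterministic for a fixed ``config.seed``.  The target is
    ``y = X beta + alpha_entity + gamma_year + eps`` with the dispersions
    stated in the config; by construction each feature has unit variance
    and ``y`` is approximately on the z-scale.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n_ent, n_yr = config.n_entities, config.n_years
    n = n_ent * n_yr
    entities = np.repeat(
        np.array([f"C{i + 1:02d}" for i in range(n_ent)]), n_yr
    )
    years = np.tile(config.years, n_ent)

    # latent group factors: entity-level component + per-row innovation
    share = config.latent_entity_share
    factors = {}
    for group in ("economic", "health"):
        u = rng.normal(0.0, 1.0, n_ent)  # entity-level
        v = rng.normal(0.0, 1.0, n)  # idiosyncratic per row
        factors[group] = np.sqrt(share) * np.repeat(u, n_yr) + np.sqrt(1 - share) * v

    X = np.empty((n, len(config.feature_names)))
    for j, name in enumerate(config.feature_names):
        lam = config.loading_of(name)
        group = config.group_map.get(name, "health")
        X[:, j] = lam * factors[group] + np.sqrt(1.0 - lam**2) * rng.normal(
            0.0, 1.0, n
        )

    beta = config.resolved_beta()
    alpha = rng.normal(0.0, config.entity_effect_sd, n_ent)
    gamma = config.resolved_year_trend()
    y = (
        X @ beta
        + np.repeat(alpha, n_yr)
        + np.tile(gamma, n_ent)
        + rng.normal(0.0, config.noise_sd, n)
    )

    Xf = pd.DataFrame(X, columns=list(config.feature_names))
    return PanelDataset(
        entity=entities,
        year=years,
        X=Xf,
        y=y,
        missing_mask=pd.DataFrame(
            False, index=Xf.index, columns=Xf.columns
        ),
        truth=config,
        truth_effects={
            "alpha": pd.Series(alpha, index=pd.unique(entities)),
            "gamma": pd.Series(gamma, index=config.years),
        },
    )


def generate_endogenous_welfare(
    panel: PanelDataset,
    rho_target: float = 0.940138,
    rho_instrument: float = 0.769063,
    seed: int = 1,
) -> PanelDataset:
    """Fill the endogenous welfare variable by analytic calibration.

    welfare = a * z(y) + b * z(instrument) + c * u with fresh standard
    normal noise u.  The weights (a, b) solve the 2 x 2 linear system that
    makes the population correlations with the target and the instrument
    equal to ``rho_target`` and ``rho_instrument`` given the empirical
    correlation between the two; c normalizes welfare to unit variance.

    Raises
    ------
    ValueError
        If the implied 3 x 3 correlation matrix is not positive
        semi-definite (the requested pair is infeasible for this panel).
    """
    for name, rho in (("rho_target", rho_target), ("rho_instrument", rho_instrument)):
        if not (-1.0 < rho < 1.0):
            raise ValueError(f"{name} must lie in (-1, 1), got {rho}")
    if panel.instrument_name not in panel.X.columns:
        raise ValueError(f"instrument column {panel.instrument_name!r} missing")

    def _z(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std()

    yz = _z(panel.y)
    zz = _z(panel.X[panel.instrument_name].to_numpy())
    r = float(np.mean(yz * zz))
    a, b = np.linalg.solve(
        np.array([[1.0, r], [r, 1.0]]), np.array([rho_target, rho_instrument])
    )
    c_sq = 1.0 - (a * rho_target + b * rho_instrument)
    if c_sq < -1e-10:
        raise ValueError(
            "infeasible correlation pair: implied covariance matrix is not "
            f"positive semi-definite (corr(y, instrument) = {r:.4f})"
        )
    c = float(np.sqrt(max(c_sq, 0.0)))
    rng = np.random.default_rng(seed)
    welfare = a * yz + b * zz + c * rng.normal(0.0, 1.0, panel.n_rows)
    out = panel.copy()
    out.welfare = welfare
    return out


def inject_missingness(
    panel: PanelDataset, spec: Mapping[str, int], seed: int = 1
) -> PanelDataset:
    """Blank exactly ``spec[feature]`` cells per feature, MCAR.

    Positions are drawn without replacement and reproducibly by seed.  The
    target is never maskable.
    """
    rng = np.random.default_rng(seed)
    out = panel.copy()
    for feature, count in spec.items():
        if feature == TARGET:
            raise ValueError("the target variable is never maskable")
        if feature not in out.X.columns:
            raise ValueError(f"unknown feature {feature!r}")
        if not 0 <= count <= panel.n_rows:
            raise ValueError(
                f"cannot mask {count} of {panel.n_rows} rows for {feature!r}"
            )
        rows = rng.choice(panel.n_rows, size=count, replace=False)
        col = out.X.columns.get_loc(feature)
        out.X.iloc[rows, col] = np.nan
        out.missing_mask.iloc[rows, col] = True
    return out
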