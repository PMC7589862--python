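"""Investigative Bayesian linear Gaussian regressions on standardized features.

Two exploratory models relate berry yield to N-P-K doses, leaf and soil
nutrient balances, pH and weather indices: one with seasonal indices over
the 2-year crop cycle (vegetative + fruit-bearing year), one with
phenological-stage indices of the fruit-bearing year only. Predictors are
centered to mean 0 and scaled to unit (population) variance so posterior
slope magnitudes are comparable across features.

The model is the conjugate Normal-Inverse-Gamma linear regression

    y | beta, s2 ~ N(X beta, s2 I),  beta | s2 ~ N(0, s2 * prior_sd^2 I),
    s2 ~ InvGamma(a0, b0)

with vague hyperparameters, so the posterior is available in closed form
and is sampled directly — no MCMC, no hierarchy, no random effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .features import DOSE_COLUMNS, balance_features
from .weather import default_stage_windows, season_window
from .features import weather_feature_table

__all__ = [
    "Standardizer",
    "PosteriorSummary",
    "BayesianLinearRegression",
    "fit_bayes_linear",
    "model_2year",
    "model_bearing_year",
]


class Standardizer:
    """Center to 0 mean, scale to unit population (divisor n) variance.

    Transform parameters are computed on the fitting rows only and can be
    applied to new rows.
    """

    def fit(self, X: pd.DataFrame) -> "Standardizer":
        X = pd.DataFrame(X)
        self.feature_names_ = list(X.columns)
        values = X.to_numpy(dtype=float)
        self.centers_ = values.mean(axis=0)
        self.scales_ = values.std(axis=0, ddof=0)
        zero = [n for n, s in zip(self.feature_names_, self.scales_) if s == 0]
        if zero:
            raise ValueError(f"zero-variance columns: {zero}")
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)[self.feature_names_]
        return (X.to_numpy(dtype=float) - self.centers_) / self.scales_

    def fit_transform(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.scales_ + self.centers_


@dataclass
class PosteriorSummary:
    """Posterior draws and moments for regression coefficients."""

    feature_names: list[str]
    draws: np.ndarray  # (n_draws, p) coefficient draws
    sigma_draws: np.ndarray  # (n_draws,) residual sd draws
    interval_level: float = 0.95

    def table(self) -> pd.DataFrame:
        alpha = (1.0 - self.interval_level) / 2.0
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "mean": self.draws.mean(axis=0),
                "sd": self.draws.std(axis=0, ddof=1),
                "lo": np.quantile(self.draws, alpha, axis=0),
                "hi": np.quantile(self.draws, 1 - alpha, axis=0),
            }
        )

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]


class BayesianLinearRegression:
    """Scikit-learn style conjugate Bayesian linear regression.

    Standardizes predictors internally (population sd); the outcome is
    centered (the intercept is profiled out rather than sampled). Posterior
    coefficient draws are exact draws from the Normal-Inverse-Gamma
    posterior.

    Parameters
    ----------
    prior_sd : float
        Prior sd of each standardized coefficient (relative to the residual
        scale). 10 is vague at crop-yield scales.
    a0, b0 : float
        Inverse-Gamma shape/scale of the residual-variance prior.
    n_draws : int
        Number of exact posterior draws.
    interval_level : float
        Central credible-interval mass for summaries.
    random_state : int
        Seed for the posterior draws.
    """

    def __init__(
        self,
        prior_sd: float = 10.0,
        a0: float = 0.001,
        b0: float = 0.001,
        n_draws: int = 2000,
        interval_level: float = 0.95,
        random_state: int = 0,
        standardize: bool = True,
    ):
        self.prior_sd = prior_sd
        self.a0 = a0
        self.b0 = b0
        self.n_draws = n_draws
        self.interval_level = interval_level
        self.random_state = random_state
        self.standardize = standardize

    def get_params(self, deep: bool = True) -> dict:
        return {
            "prior_sd": self.prior_sd,
            "a0": self.a0,
            "b0": self.b0,
            "n_draws": self.n_draws,
            "interval_level": self.interval_level,
            "random_state": self.random_state,
            "standardize": self.standardize,
        }

    def set_params(self, **params) -> "BayesianLinearRegression":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y) -> "BayesianLinearRegression":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n != y.size:
            raise ValueError(f"{n} rows but {y.size} outcomes")
        if n <= p:
            raise ValueError(f"need more rows ({n}) than coefficients ({p})")
        if self.standardize:
            self.scaler_ = Standardizer().fit(X)
            Z = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Z = X.to_numpy(dtype=float)
        self.feature_names_in_ = list(X.columns)
        if np.linalg.matrix_rank(Z) < p:
            raise ValueError(
                f"rank-deficient design; collinear columns: "
                f"{_collinear_columns(Z, self.feature_names_in_)}"
            )
        self.y_center_ = y.mean()
        yc = y - self.y_center_

        v0_inv = np.eye(p) / self.prior_sd**2
        vn_inv = v0_inv + Z.T @ Z
        vn = linalg.inv(vn_inv)
        vn = (vn + vn.T) / 2.0
        mn = vn @ (Z.T @ yc)
        an = self.a0 + n / 2.0
        bn = self.b0 + 0.5 * (yc @ yc - mn @ vn_inv @ mn)

        rng = np.random.default_rng(self.random_state)
        sigma2 = bn / rng.gamma(an, 1.0, size=self.n_draws)
        chol = linalg.cholesky(vn, lower=True)
        eps = rng.standard_normal((self.n_draws, p))
        draws = mn + np.sqrt(sigma2)[:, None] * (eps @ chol.T)

        self.coef_ = mn
        self.posterior_ = PosteriorSummary(
            self.feature_names_in_, draws, np.sqrt(sigma2), self.interval_level
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Z = (
            self.scaler_.transform(pd.DataFrame(X))
            if self.scaler_ is not None
            else pd.DataFrame(X).to_numpy(dtype=float)
        )
        return self.y_center_ + Z @ self.coef_

    def summary(self) -> pd.DataFrame:
        return self.posterior_.table()


def fit_bayes_linear(
    X,
    y,
    prior_sd: float = 10.0,
    n_draws: int = 2000,
    seed: int = 0,
    **kwargs,
) -> PosteriorSummary:
    """Functional wrapper: fit the conjugate model, return the posterior."""
    model = BayesianLinearRegression(
        prior_sd=prior_sd, n_draws=n_draws, random_state=seed, **kwargs
    )
    return model.fit(pd.DataFrame(X), y).posterior_


def _seasonal_design(obs: pd.DataFrame, weather_df: pd.DataFrame) -> pd.DataFrame:
    """Seasonal (April-August) indices for bearing and vegetative years."""
    window = [season_window()]
    bearing = weather_feature_table(
        obs, weather_df, kind="stage", windows=window, prefix="bearing "
    )
    veg_obs = obs[["site", "year"]].copy()
    veg_obs["year"] = veg_obs["year"] - 1
    vegetative = weather_feature_table(
        veg_obs, weather_df, kind="stage", windows=window, prefix="vegetative "
    )
    out = pd.concat([bearing, vegetative], axis=1)
    out.columns = [c.replace(f"{season_window().name}_", "") for c in out.columns]
    return out


def model_2year(
    obs: pd.DataFrame, weather_df: pd.DataFrame, **kwargs
) -> BayesianLinearRegression:
    """Yield on doses, 2-year seasonal weather, balances and pH (21 features)."""
    _require(obs, DOSE_COLUMNS + ["pH", "yield", "site", "year"])
    design = pd.concat(
        [
            obs[DOSE_COLUMNS],
            _seasonal_design(obs, weather_df),
            balance_features(obs),
            obs[["pH"]],
        ],
        axis=1,
    )
    model = BayesianLinearRegression(**kwargs)
    return model.fit(design, obs["yield"])


def model_bearing_year(
    obs: pd.DataFrame, weather_df: pd.DataFrame, **kwargs
) -> BayesianLinearRegression:
    """Yield on doses, bearing-year stage weather, balances and pH.

    Freezing days enter only for the earliest stage (before flower-bud
    opening): later windows essentially never freeze, so the count is
    degenerate there.
    """
    _require(obs, DOSE_COLUMNS + ["pH", "yield", "site", "year"])
    earliest = default_stage_windows()[0].name
    stage = weather_feature_table(
        obs,
        weather_df,
        kind="stage",
        prefix="stage ",
        freezing_for={earliest},
    )
    design = pd.concat(
        [obs[DOSE_COLUMNS], stage, balance_features(obs), obs[["pH"]]],
        axis=1,
    )
    model = BayesianLinearRegression(**kwargs)
    return model.fit(design, obs["yield"])


def _require(obs: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table lacks columns {missing}")
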