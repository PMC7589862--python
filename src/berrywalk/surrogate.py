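"""Gaussian-process yield surrogate with an applicability-domain envelope.

The predictive model: a 70/30 train/test split, feature and outcome
standardization on the training rows only, an RBF + white-noise Gaussian
process fitted by restarted marginal-likelihood maximization, regression
metrics (RMSE, R2) and a classification mode at a profitability yield
cutoff (5000 kg/ha), where the positive class is the LOW yielder.

The fitted model also stores the training envelope — feature mean,
covariance (with escalating ridge jitter) and per-feature min/max in
standardized space — which the optimizer uses to reject extrapolating
candidate states.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .investigative import Standardizer

__all__ = [
    "SplitSpec",
    "split",
    "TrainingEnvelope",
    "YieldSurrogate",
    "fit_gp",
    "regression_metrics",
    "classification_report_at_cutoff",
    "ClassificationReport",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitSpec:
    """A reproducible uniform train/test row split."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float
    seed: int


def split(n_rows: int, fraction: float = 0.7, seed: int = 0) -> SplitSpec:
    """Uniform random split of ``n_rows`` into train/test index sets."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    n_train = int(round(n_rows * fraction))
    if n_train == 0 or n_train == n_rows:
        raise ValueError(f"{n_rows} rows leave an empty split at {fraction}")
    perm = np.random.default_rng(seed).permutation(n_rows)
    return SplitSpec(np.sort(perm[:n_train]), np.sort(perm[n_train:]), fraction, seed)


@dataclass
class TrainingEnvelope:
    """Mean, covariance and per-feature bounds of the training features
    (standardized space); the optimizer's applicability domain."""

    center: np.ndarray
    covariance: np.ndarray
    mins: np.ndarray
    maxs: np.ndarray
    jitter: float = 0.0
    _chol: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_rows(cls, Z: np.ndarray, jitter0: float = 1e-8) -> "TrainingEnvelope":
        Z = np.asarray(Z, dtype=float)
        cov = np.cov(Z, rowvar=False)
        cov = np.atleast_2d((cov + cov.T) / 2.0)
        jitter = 0.0
        trial = jitter0
        while True:
            try:
                chol = linalg.cholesky(cov + jitter * np.eye(cov.shape[0]), lower=True)
                break
            except linalg.LinAlgError:
                jitter = trial
                trial *= 10.0
                if jitter > 1e-2:
                    raise
                logger.info("envelope covariance jitter escalated to %g", jitter)
        env = cls(
            Z.mean(axis=0), cov, Z.min(axis=0), Z.max(axis=0), jitter
        )
        env._chol = chol
        return env

    def mahalanobis(self, Z: np.ndarray) -> np.ndarray:
        """Mahalanobis distance of each row from the training centroid."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        diff = Z - self.center
        sol = linalg.solve_triangular(self._chol, diff.T, lower=True)
        return np.sqrt((sol**2).sum(axis=0))

    def within_bounds(self, Z: np.ndarray, free_idx=None) -> np.ndarray:
        """True where every (free) feature sits inside training min/max."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        idx = np.arange(Z.shape[1]) if free_idx is None else np.asarray(free_idx)
        lo = self.mins[idx]
        hi = self.maxs[idx]
        return ((Z[:, idx] >= lo) & (Z[:, idx] <= hi)).all(axis=1)

    def critical_distance(self, quantile: float = 0.975) -> float:
        """sqrt of the chi-square quantile at the feature dimension."""
        return float(np.sqrt(stats.chi2.ppf(quantile, df=self.center.size)))


class YieldSurrogate:
    """Scikit-learn style GP yield surrogate.

    Fits a ``ConstantKernel * RBF + WhiteKernel`` Gaussian process on
    features and outcome standardized to the training rows, with
    ``n_restarts`` restarted maximizations of the log marginal likelihood.

    Parameters
    ----------
    n_restarts : int
        Extra random restarts of the hyperparameter optimization.
    random_state : int
        Seed for restarts (the fit is deterministic given data and seed).
    anisotropic : bool
        Use one length-scale per feature (ARD) instead of a single
        isotropic length-scale.
    """

    def __init__(
        self,
        n_restarts: int = 4,
        random_state: int = 0,
        anisotropic: bool = False,
        min_train_rows: int = 10,
    ):
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.anisotropic = anisotropic
        self.min_train_rows = min_train_rows

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_restarts": self.n_restarts,
            "random_state": self.random_state,
            "anisotropic": self.anisotropic,
            "min_train_rows": self.min_train_rows,
        }

    def set_params(self, **params) -> "YieldSurrogate":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y) -> "YieldSurrogate":
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        if len(X) < self.min_train_rows:
            raise ValueError(
                f"need at least {self.min_train_rows} training rows, got {len(X)}"
            )
        if not np.isfinite(X.to_numpy(dtype=float)).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in training data")
        self.feature_names_in_ = list(X.columns)
        self.scaler_ = Standardizer().fit(X)
        Z = self.scaler_.transform(X)
        self.y_center_ = float(y.mean())
        self.y_scale_ = float(y.std(ddof=0))
        if self.y_scale_ == 0:
            self.y_scale_ = 1.0
        yz = (y - self.y_center_) / self.y_scale_

        length0 = np.ones(Z.shape[1]) if self.anisotropic else 1.0
        kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
            length0, (1e-2, 1e3)
        ) + WhiteKernel(0.1, (1e-10, 1e2))
        self.gp_ = GaussianProcessRegressor(
            kernel=kernel,
            n_restarts_optimizer=self.n_restarts,
            normalize_y=False,
            random_state=self.random_state,
        )
        self.gp_.fit(Z, yz)
        self.kernel_ = self.gp_.kernel_
        self.envelope_ = TrainingEnvelope.from_rows(Z)
        return self

    def _check_columns(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"missing features {missing}")
        return X[self.feature_names_in_]

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Rows mapped into the surrogate's standardized feature space."""
        return self.scaler_.transform(self._check_columns(pd.DataFrame(X)))

    def inverse_transform(self, Z: np.ndarray) -> pd.DataFrame:
        raw = self.scaler_.inverse_transform(np.atleast_2d(Z))
        return pd.DataFrame(raw, columns=self.feature_names_in_)

    def predict(self, X: pd.DataFrame, return_std: bool = False):
        """De-standardized yield predictions (kg/ha), optionally with sd."""
        Z = self.transform(pd.DataFrame(X))
        return self.predict_standardized(Z, return_std=return_std)

    def predict_standardized(self, Z: np.ndarray, return_std: bool = False):
        """Predict from points already in standardized feature space."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if return_std:
            mu, sd = self.gp_.predict(Z, return_std=True)
            return self.y_center_ + self.y_scale_ * mu, self.y_scale_ * sd
        return self.y_center_ + self.y_scale_ * self.gp_.predict(Z)

    def to_json(self) -> str:
        """Hyperparameters, scalings and envelope (not the GP dual weights)."""
        return json.dumps(
            {
                "kernel": str(self.kernel_),
                "theta": self.gp_.kernel_.theta.tolist(),
                "feature_names": self.feature_names_in_,
                "x_centers": self.scaler_.centers_.tolist(),
                "x_scales": self.scaler_.scales_.tolist(),
                "y_center": self.y_center_,
                "y_scale": self.y_scale_,
                "envelope": {
                    "center": self.envelope_.center.tolist(),
                    "covariance": self.envelope_.covariance.tolist(),
                    "mins": self.envelope_.mins.tolist(),
                    "maxs": self.envelope_.maxs.tolist(),
                    "jitter": self.envelope_.jitter,
                },
            },
            indent=2,
        )


def fit_gp(
    X: pd.DataFrame, y, n_restarts: int = 4, seed: int = 0, **kwargs
) -> YieldSurrogate:
    """Functional wrapper over :class:`YieldSurrogate`."""
    return YieldSurrogate(
        n_restarts=n_restarts, random_state=seed, **kwargs
    ).fit(X, y)


def regression_metrics(pred, obs) -> dict[str, float]:
    """RMSE (same units as the outcome) and R2 = 1 - SSE/SST."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size or pred.size < 2:
        raise ValueError("pred and obs must have equal length >= 2")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    sst = float(((obs - obs.mean()) ** 2).sum())
    if sst == 0:
        logger.warning("zero-variance observations: R2 undefined")
        return {"rmse": rmse, "r2": float("nan")}
    return {"rmse": rmse, "r2": 1.0 - float(((obs - pred) ** 2).sum()) / sst}


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts at a yield cutoff; positive class = low yielder."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def positive_predictive_rate(self) -> float:
        if self.tp + self.fp == 0:
            logger.warning("no predicted low yielders: PPV undefined")
            return float("nan")
        return self.tp / (self.tp + self.fp)

    @property
    def negative_predictive_rate(self) -> float:
        if self.tn + self.fn == 0:
            logger.warning("no predicted high yielders: NPV undefined")
            return float("nan")
        return self.tn / (self.tn + self.fn)


def classification_report_at_cutoff(
    pred, obs, cutoff: float = 5000.0
) -> ClassificationReport:
    """Classify low (< cutoff) vs high yielders from continuous predictions."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size != obs.size:
        raise ValueError("pred and obs must have equal length")
    pred_low = pred < cutoff
    obs_low = obs < cutoff
    return ClassificationReport(
        cutoff=cutoff,
        tp=int((pred_low & obs_low).sum()),
        fp=int((pred_low & ~obs_low).sum()),
        tn=int((~pred_low & ~obs_low).sum()),
        fn=int((~pred_low & obs_low).sum()),
    )
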