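"""Conjugate Bayesian linear regression (Normal–Inverse-Gamma).

The model is ``y = X beta + eps``, ``eps ~ N(0, sigma^2)``, with the
conjugate prior

    beta | sigma^2 ~ N(0, sigma^2 * Lambda0^-1),   sigma^2 ~ InvGamma(a0, b0)

applied on standardized predictors and a standardized response.  With a
unit prior precision per standardized coefficient this matches a
weakly-informative N(0, 1) coefficient prior at the residual scales that
arise in practice (standardized responses have sigma <= 1), while keeping
the posterior in closed form: marginal coefficient and posterior-predictive
distributions are Student-t, so all summaries are deterministic — no
Monte-Carlo error, exact reproducibility.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = ["ConjugateLinearModel", "CoefficientSummary"]


@dataclass
class CoefficientSummary:
    names: list
    mean: np.ndarray   # posterior means, original predictor units
    sd: np.ndarray     # posterior sds, original predictor units

    def as_dict(self) -> dict:
        return {
            n: {"mean": float(m), "sd": float(s)}
            for n, m, s in zip(self.names, self.mean, self.sd)
        }


@dataclass
class ConjugateLinearModel:
    """Bayesian linear regression with closed-form posterior.

    Parameters
    ----------
    coef_prior_precision:
        Prior precision of each standardized slope (1.0 -> N(0, sigma^2) prior).
    intercept_prior_precision:
        Prior precision of the intercept on the standardized response scale
        (0.25 -> prior sd 2).
    a0, b0:
        Inverse-Gamma hyperparameters of the residual variance; the defaults
        are vague.
    """

    coef_prior_precision: float = 1.0
    intercept_prior_precision: float = 0.25
    a0: float = 0.1
    b0: float = 0.1

    # fitted state
    _mu: np.ndarray = field(default=None, repr=False)
    _cov_factor: np.ndarray = field(default=None, repr=False)  # Lambda_n^-1
    _an: float = field(default=None, repr=False)
    _bn: float = field(default=None, repr=False)
    _x_mean: np.ndarray = field(default=None, repr=False)
    _x_sd: np.ndarray = field(default=None, repr=False)
    _y_mean: float = field(default=None, repr=False)
    _y_sd: float = field(default=None, repr=False)
    n_obs: int = field(default=0, repr=False)
    feature_names: list = field(default=None, repr=False)

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, feature_names=None) -> "ConjugateLinearModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise DomainError("X must be 2-D")
        if len(y) != X.shape[0]:
            raise DomainError("X and y lengths differ")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise DomainError("non-finite values in training data")
        n, p = X.shape
        if np.std(y) == 0:
            raise DomainError("constant target: nothing to regress")

        self._x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant columns: centered to 0, slope pinned by prior
        self._x_sd = sd
        self._y_mean = float(y.mean())
        self._y_sd = float(y.std())

        Z = (X - self._x_mean) / self._x_sd
        ys = (y - self._y_mean) / self._y_sd
        D = np.column_stack([np.ones(n), Z])

        lam0 = np.diag(
            [self.intercept_prior_precision] + [self.coef_prior_precision] * p
        )
        lam_n = D.T @ D + lam0
        lam_n_inv = np.linalg.inv(lam_n)
        mu = lam_n_inv @ (D.T @ ys)

        self._mu = mu
        self._cov_factor = lam_n_inv
        self._an = self.a0 + n / 2.0
        self._bn = self.b0 + 0.5 * float(ys @ ys - mu @ lam_n @ mu)
        self.n_obs = n
        self.feature_names = (
            list(feature_names) if feature_names is not None else [f"x{i}" for i in range(p)]
        )
        return self

    # ------------------------------------------------------------- summaries
    @property
    def df(self) -> float:
        return 2.0 * self._an

    @property
    def residual_scale(self) -> float:
        """Posterior mean of sigma (original y units)."""
        return float(np.sqrt(self._bn / (self._an - 1.0)) * self._y_sd)

    def coefficient_summary(self) -> CoefficientSummary:
        """Slope posteriors mapped back to original predictor/response units."""
        var = self._bn / (self._an - 1.0) * np.diag(self._cov_factor)
        mean_std = self._mu[1:]
        sd_std = np.sqrt(var[1:])
        scale = self._y_sd / self._x_sd
        return CoefficientSummary(self.feature_names, mean_std * scale, sd_std * scale)

    def coefficient_interval(self, j: int, level: float = 0.95) -> tuple:
        """Central credible interval for slope ``j`` (original units)."""
        t = stats.t.ppf(0.5 * (1 + level), self.df)
        idx = j + 1
        scale_t = np.sqrt(self._bn / self._an * self._cov_factor[idx, idx])
        mean = self._mu[idx]
        lo, hi = mean - t * scale_t, mean + t * scale_t
        f = self._y_sd / self._x_sd[j]
        return lo * f, hi * f

    # ---------------------------------------------------------------- predict
    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self._x_sd):
            raise DomainError(
                f"feature length mismatch: expected {len(self._x_sd)}, got {X.shape[1]}"
            )
        Z = (X - self._x_mean) / self._x_sd
        return np.column_stack([np.ones(len(Z)), Z])

    def predict(self, X, level: float = 0.9):
        """Posterior-predictive mean and central interval (original y units).

        Returns ``(mean, lo, hi)`` arrays.
        """
        D = self._design(X)
        mean_std = D @ self._mu
        leverage = np.einsum("ij,jk,ik->i", D, self._cov_factor, D)
        scale = np.sqrt(self._bn / self._an * (1.0 + leverage))
        t = stats.t.ppf(0.5 * (1 + level), self.df)
        mean = mean_std * self._y_sd + self._y_mean
        lo = (mean_std - t * scale) * self._y_sd + self._y_mean
        hi = (mean_std + t * scale) * self._y_sd + self._y_mean
        return mean, lo, hi
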