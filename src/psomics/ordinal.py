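"""Proportional-odds (cumulative logit) regression.

The model is

    P(Y <= l | x) = sigma(theta_l - x' beta),   l = 1, ..., L-1,

with strictly increasing thresholds theta and a common slope vector beta
across all cumulative splits.  Under this sign convention a *positive* slope
shifts probability mass toward *higher* (worse) outcome categories; every
downstream weight in the package inherits that convention.

``OrderedLogit`` follows the statsmodels model/results idiom: construct from
data, call :meth:`OrderedLogit.fit`, and read estimates, standard errors and
diagnostics off the returned :class:`OrderedLogitResults`.

The likelihood is maximized by L-BFGS with an analytic gradient, in a
reparameterized space (first threshold plus log-increments) that enforces
threshold monotonicity by construction.  A tiny ridge penalty on the slopes
(``ridge_eps``, default 1e-8) keeps the optimum finite under complete
separation; it is part of the fitting contract, not a tuning knob.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

__all__ = ["OrderedLogit", "OrderedLogitResults", "fit_propodds", "null_thresholds"]

_PFLOOR = 1e-300


def null_thresholds(counts: np.ndarray) -> np.ndarray:
    """Closed-form MLE thresholds of the predictor-free model.

    With level counts ``n_0..n_{L-1}`` the fitted cumulative probabilities are
    the empirical ones, so ``theta_l = logit(cumsum(n)_l / n)``.
    """
    counts = np.asarray(counts, dtype=float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return np.log(cum / (1.0 - cum))


def _drop_empty_levels(codes: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Renumber codes so every level 0..L'-1 is observed; returns (codes, kept)."""
    kept = np.flatnonzero(np.bincount(codes, minlength=n_levels) > 0)
    remap = np.full(n_levels, -1)
    remap[kept] = np.arange(kept.size)
    return remap[codes], kept


class OrderedLogit:
    """Proportional-odds model for an integer-coded ordinal outcome.

    Parameters
    ----------
    endog : array-like of int
        Outcome codes 0..L-1.  Unobserved levels are dropped (renumbered)
        before fitting, because the cumulative logit is undefined for empty
        categories.
    exog : array-like or None
        Predictor matrix (n x p), or None for the thresholds-only null model.
    n_levels : int, optional
        Declared number of levels; defaults to ``max(endog) + 1``.
    ridge_eps : float
        Ridge penalty coefficient on the slopes.
    """

    def __init__(self, endog, exog=None, n_levels: int | None = None,
                 ridge_eps: float = 1e-8):
        codes = np.asarray(endog, dtype=int)
        if codes.ndim != 1:
            raise ValueError("endog must be 1-D integer codes")
        n_levels = int(n_levels if n_levels is not None else codes.max() + 1)
        self.endog, self._kept_levels = _drop_empty_levels(codes, n_levels)
        self.n_levels = int(self._kept_levels.size)
        if self.n_levels < 2:
            raise ValueError("outcome has fewer than 2 observed levels")
        if exog is None:
            exog = np.empty((codes.size, 0))
        self.exog_names = (
            list(exog.columns) if isinstance(exog, pd.DataFrame)
            else [f"x{j}" for j in range(np.asarray(exog).shape[1])]
        )
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != codes.size:
            raise ValueError("exog must be 2-D with one row per observation")
        if not np.all(np.isfinite(self.exog)):
            raise ValueError("exog contains non-finite values")
        self.nobs = codes.size
        self.k_exog = self.exog.shape[1]
        self.ridge_eps = float(ridge_eps)

    # ---- likelihood in raw (thresholds, beta) space -----------------------

    def _ab(self, thresholds, beta):
        eta = self.exog @ beta if self.k_exog else np.zeros(self.nobs)
        ext = np.concatenate(([-np.inf], thresholds, [np.inf]))
        return ext[self.endog + 1] - eta, ext[self.endog] - eta

    def loglike(self, thresholds, beta) -> float:
        """Exact log-likelihood at the given raw parameters (no penalty)."""
        a, b = self._ab(np.asarray(thresholds, float), np.asarray(beta, float))
        p = np.clip(expit(a) - expit(b), _PFLOOR, None)
        return float(np.log(p).sum())

    def _loglike_grad_raw(self, thresholds, beta):
        """Log-likelihood and its gradient wrt (thresholds, beta)."""
        a, b = self._ab(thresholds, beta)
        A, B = expit(a), expit(b)
        p = np.clip(A - B, _PFLOOR, None)
        fA = np.where(np.isfinite(a), A * (1.0 - A), 0.0)
        fB = np.where(np.isfinite(b), B * (1.0 - B), 0.0)
        wA, wB = fA / p, fB / p
        g_thr = np.zeros(self.n_levels - 1)
        upper = self.endog <= self.n_levels - 2  # obs whose a uses theta[endog]
        np.add.at(g_thr, self.endog[upper], wA[upper])
        lower = self.endog >= 1  # obs whose b uses theta[endog-1]
        np.subtract.at(g_thr, self.endog[lower] - 1, wB[lower])
        g_eta = wB - wA
        g_beta = self.exog.T @ g_eta if self.k_exog else np.zeros(0)
        return float(np.log(p).sum()), g_thr, g_beta

    # ---- transformed space: t = (theta_1, log increments, beta) ----------

    def _unpack(self, t):
        L = self.n_levels
        incr = np.exp(t[1:L - 1])
        thresholds = t[0] + np.concatenate(([0.0], np.cumsum(incr)))
        return thresholds, t[L - 1:]

    def loglike_grad_t(self, t):
        """Unpenalized log-likelihood and gradient in the transformed space
        (first threshold, log-increments, slopes).  Shared with the penalized
        fitters in :mod:`psomics.selection`."""
        thresholds, beta = self._unpack(t)
        ll, g_thr, g_beta = self._loglike_grad_raw(thresholds, beta)
        L = self.n_levels
        g = np.empty_like(t)
        g[0] = g_thr.sum()
        if L > 2:
            tail = np.cumsum(g_thr[::-1])[::-1]  # sum_{j>=k} dll/dtheta_j
            g[1:L - 1] = np.exp(t[1:L - 1]) * tail[1:]
        g[L - 1:] = g_beta
        return ll, g

    def _negloglike_grad_t(self, t):
        ll, g = self.loglike_grad_t(t)
        beta = t[self.n_levels - 1:]
        obj = -ll + self.ridge_eps * float(beta @ beta)
        g = -g
        g[self.n_levels - 1:] += 2.0 * self.ridge_eps * beta
        return obj, g

    def fit(self, maxiter: int = 500, gtol: float = 1e-8,
            start_params: np.ndarray | None = None) -> "OrderedLogitResults":
        counts = np.bincount(self.endog, minlength=self.n_levels)
        thr0 = null_thresholds(counts)
        t0 = np.concatenate(([thr0[0]], np.log(np.maximum(np.diff(thr0), 1e-8)),
                             np.zeros(self.k_exog)))
        if start_params is not None:
            t0 = np.asarray(start_params, dtype=float)
        res = minimize(self._negloglike_grad_t, t0, jac=True, method="L-BFGS-B",
                       options={"maxiter": maxiter, "gtol": gtol, "ftol": 0.0,
                                "maxcor": 20})
        thresholds, beta = self._unpack(res.x)
        _, g_thr, g_beta = self._loglike_grad_raw(thresholds, beta)
        grad = np.concatenate((g_thr, g_beta - 2.0 * self.ridge_eps * beta))
        converged = bool(np.max(np.abs(grad)) < 1e-5 or res.success)
        if not converged:
            warnings.warn("proportional-odds fit did not converge", RuntimeWarning)
        return OrderedLogitResults(
            model=self, thresholds=thresholds, params=beta,
            llf=self.loglike(thresholds, beta), converged=converged,
            transformed_params=res.x,
        )


@dataclass
class OrderedLogitResults:
    """Fit results: thresholds, slopes, log-likelihood, inference helpers."""

    model: OrderedLogit
    thresholds: np.ndarray
    params: np.ndarray
    llf: float
    converged: bool
    transformed_params: np.ndarray
    _cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    def _raw(self) -> np.ndarray:
        return np.concatenate((self.thresholds, self.params))

    def _neg_grad_raw(self, r: np.ndarray) -> np.ndarray:
        L = self.model.n_levels
        _, g_thr, g_beta = self.model._loglike_grad_raw(r[:L - 1], r[L - 1:])
        return -np.concatenate((g_thr, g_beta - 2.0 * self.model.ridge_eps * r[L - 1:]))

    def cov_params(self) -> np.ndarray:
        """Observed-information covariance via finite differences of the
        analytic gradient."""
        if self._cov is None:
            r = self._raw()
            k = r.size
            H = np.empty((k, k))
            h = 1e-5 * np.maximum(1.0, np.abs(r))
            for j in range(k):
                rp, rm = r.copy(), r.copy()
                rp[j] += h[j]
                rm[j] -= h[j]
                H[:, j] = (self._neg_grad_raw(rp) - self._neg_grad_raw(rm)) / (2 * h[j])
            H = 0.5 * (H + H.T)
            self._cov = np.linalg.pinv(H)
        return self._cov

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the slopes."""
        L = self.model.n_levels
        var = np.diag(self.cov_params())[L - 1:]
        return np.sqrt(np.clip(var, 0.0, None))

    @property
    def pvalues(self) -> np.ndarray:
        """Two-sided Wald p-values of the slopes."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.bse > 0, self.params / self.bse, np.inf)
        return 2.0 * norm.sf(np.abs(z))

    def predict_proba(self, exog) -> np.ndarray:
        """Per-class probabilities (n x L) at the fitted parameters."""
        X = np.asarray(exog, dtype=float)
        eta = X @ self.params if self.model.k_exog else np.zeros(X.shape[0])
        ext = np.concatenate(([-np.inf], self.thresholds, [np.inf]))
        cum = expit(ext[None, :] - eta[:, None])
        return np.diff(cum, axis=1)

    def loglike_on(self, exog, endog) -> float:
        """Log-likelihood of new data at the fitted parameters.

        The new codes must use the same (renumbered) coding as the fit; codes
        beyond the fitted level range are a caller error.
        """
        codes = np.asarray(endog, dtype=int)
        if codes.size and codes.max() >= self.model.n_levels:
            raise ValueError("endog codes exceed the fitted level range")
        m = OrderedLogit.__new__(OrderedLogit)
        m.endog, m.n_levels = codes, self.model.n_levels
        m.exog = (np.asarray(exog, dtype=float) if exog is not None
                  else np.empty((codes.size, 0)))
        m.k_exog, m.nobs = m.exog.shape[1], codes.size
        return OrderedLogit.loglike(m, self.thresholds, self.params)

    def summary(self) -> str:
        lines = [
            "Proportional-odds (cumulative logit) regression",
            f"  nobs: {self.model.nobs}   levels: {self.model.n_levels}   "
            f"log-likelihood: {self.llf:.4f}   converged: {self.converged}",
            "  thresholds: " + ", ".join(f"{t:.4f}" for t in self.thresholds),
        ]
        if self.model.k_exog:
            tab = pd.DataFrame({
                "coef": self.params, "std err": self.bse, "P>|z|": self.pvalues,
            }, index=self.exog_names)
            lines.append(tab.to_string(float_format=lambda v: f"{v: .4f}"))
        return "\n".join(lines)


def fit_propodds(X, y, n_levels: int | None = None, ridge_eps: float = 1e-8,
                 **fit_kw) -> OrderedLogitResults:
    """Convenience wrapper: build an :class:`OrderedLogit` and fit it.

    ``X`` may be None for the thresholds-only null model; ``y`` is integer
    codes or an object with a ``codes`` attribute.
    """
    codes = getattr(y, "codes", y)
    levels = n_levels if n_levels is not None else getattr(y, "n_levels", None)
    return OrderedLogit(np.asarray(codes, dtype=int), X, n_levels=levels,
                        ridge_eps=ridge_eps).fit(**fit_kw)
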