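"""Unpenalized logistic fits for stepwise refinement and cross-validation.

statsmodels' Newton MLE is the primary route. With n = 40 and strong
markers, (quasi-)complete separation is a live possibility; a separated or
non-converged fit is re-run with a tiny ridge (1e-6 on the slope block of
the Hessian, intercept untouched) and flagged, so downstream consumers can
report it rather than silently diverging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

try:  # raised (older statsmodels) or warned (newer); handle both
    from statsmodels.tools.sm_exceptions import PerfectSeparationError
except ImportError:  # pragma: no cover
    class PerfectSeparationError(Exception):
        pass

#: coefficient magnitude beyond which a standardized-predictor logistic fit
#: is treated as diverging toward separation
_SEPARATION_BETA = 15.0


@dataclass
class LogisticFit:
    """MLE (or ridge-stabilized) logistic fit: intercept + slopes."""

    intercept: float
    coef: np.ndarray
    llf: float
    converged: bool
    separation: bool
    ridged: bool

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, dtype=float) @ self.coef
        return expit(eta)


def _log_likelihood(intercept: float, coef: np.ndarray, X: np.ndarray,
                    y: np.ndarray) -> float:
    eta = intercept + X @ coef
    # log(1+e^eta) computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _ridge_newton(X: np.ndarray, y: np.ndarray, ridge: float,
                  tol: float = 1e-10, max_iter: int = 200) -> tuple[np.ndarray, bool]:
    """Newton-Raphson with step halving; ridge penalizes slopes only."""
    n, k = X.shape
    Xd = np.column_stack([np.ones(n), X])
    pen = np.diag(np.r_[0.0, np.full(k, ridge)])
    beta = np.zeros(k + 1)

    def objective(b):
        eta = Xd @ b
        return np.sum(y * eta - np.logaddexp(0.0, eta)) - 0.5 * ridge * np.sum(b[1:] ** 2)

    obj = objective(beta)
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = expit(eta)
        grad = Xd.T @ (y - mu) - pen @ beta
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        hess = (Xd * w[:, None]).T @ Xd + pen
        step = np.linalg.solve(hess, grad)
        # halve until the penalized log-likelihood does not decrease
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                break
            t /= 2.0
        beta, prev_obj, obj = cand, obj, cand_obj
        if np.max(np.abs(grad)) < tol or abs(obj - prev_obj) < tol:
            converged = True
            break
    return beta, converged


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge_fallback: float = 1e-6,
                 max_iter: int = 100) -> LogisticFit:
    """Fit an unpenalized logistic regression, stabilizing separation.

    ``X`` is ``(n, k)`` (k may be 0 for an intercept-only model); ``y`` is
    binary. Returns the MLE when it exists; otherwise a fit with ridge
    ``ridge_fallback`` on the slopes, with ``separation``/``ridged`` flagged.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    y = np.asarray(y, dtype=float)
    n, k = X.shape

    if k == 0:
        pbar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
        intercept = float(np.log(pbar / (1 - pbar)))
        llf = _log_likelihood(intercept, np.zeros(0), X, y)
        return LogisticFit(intercept, np.zeros(0), llf, True, False, False)

    separation = False
    params = None
    converged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, sm.add_constant(X, has_constant="add")).fit(
                disp=0, maxiter=max_iter, method="newton"
            )
            params = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
        if any(issubclass(w.category, (PerfectSeparationWarning, RuntimeWarning))
               for w in caught):
            separation = True

    if params is not None and np.max(np.abs(params[1:])) > _SEPARATION_BETA:
        separation = True
    if params is None or separation or not converged:
        beta, conv = _ridge_newton(X, y, ridge_fallback)
        llf = _log_likelihood(beta[0], beta[1:], X, y)
        return LogisticFit(float(beta[0]), beta[1:], llf, conv, separation, True)

    intercept, coef = float(params[0]), params[1:]
    llf = _log_likelihood(intercept, coef, X, y)
    return LogisticFit(intercept, coef, llf, True, False, False)


def aic(llf: float, n_markers: int) -> float:
    """Akaike information criterion, -2 logL + 2 (k+1), intercept counted."""
    return -2.0 * llf + 2.0 * (n_markers + 1)
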