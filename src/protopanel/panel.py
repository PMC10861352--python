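"""Lasso-penalized logistic panel selection and AIC refinement.

The screened markers (already standardized to unit SD) enter an
L1-penalized logistic regression minimizing

    (1/n) * sum_i -loglik_i(beta0, beta)  +  lambda * ||beta||_1

with the intercept unpenalized and no internal re-standardization, so the
coefficients stay on the per-1-SD scale that makes exp(beta) the odds-ratio
factor per SD of a marker. The penalty weight is chosen by one of three
strategies:

* ``"cv"`` (default): stratified k-fold cross-validated deviance, lambda at
  the minimum mean held-out deviance (largest lambda wins ties);
* ``"support_size:K"``: the largest lambda on the path whose support has
  exactly K markers — useful to emulate a selection of a known size;
* ``"fixed:V"``: a fixed lambda V >= 0 (0 = the unpenalized MLE).

The lasso support is then refined by backward stepwise elimination under
AIC = -2 logL + 2 (k+1) using unpenalized refits: at each step the single
marker whose removal lowers AIC the most is dropped, until no removal
lowers AIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from ._glm import aic, fit_logistic
from ._lasso import fit_l1_logistic
from .evaluate import ClassificationMetrics, empirical_auc
from .io import GroupLabels

#: |beta| below this is "excluded by the lasso"; above it, retained even if
#: tiny (distinguishes a shrunk-to-zero coefficient from a near-zero one)
DEFAULT_COEF_TOL = 1e-8


@dataclass
class LogisticPanelModel:
    """Intercept + per-marker coefficients of a (possibly penalized) fit."""

    intercept: float
    coefficients: dict[str, float]
    lam: float | None = None
    fit_meta: dict = field(default_factory=dict)
    marker_auc: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        bad = [m for m, b in self.coefficients.items() if not np.isfinite(b)]
        if bad:
            raise ValueError(f"non-finite coefficient(s): {bad}")
        if self.lam is not None and self.lam < 0:
            raise ValueError("lambda must be >= 0")


def odds_ratio_factor(beta: float) -> float:
    """exp(beta): multiplicative odds change per 1-SD increase of the marker."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return math.exp(beta)


def nonzero_support(model: LogisticPanelModel, tol: float = DEFAULT_COEF_TOL
                    ) -> list[str]:
    """Markers with |beta| > tol, ordered by descending AUC then |beta|."""
    kept = [(m, b) for m, b in model.coefficients.items() if abs(b) > tol]
    auc = model.marker_auc or {}
    return [m for m, _ in sorted(
        kept, key=lambda mb: (-auc.get(mb[0], 0.0), -abs(mb[1]), mb[0])
    )]


def predict_proba(model: LogisticPanelModel, X) -> np.ndarray:
    """logistic(intercept + sum_j beta_j x_ij) per subject.

    ``X`` is a DataFrame (columns must cover the model's markers) or a
    mapping marker -> value for a single subject.
    """
    markers = list(model.coefficients)
    if isinstance(X, dict):
        X = pd.DataFrame([X])
    if isinstance(X, pd.DataFrame):
        missing = [m for m in markers if m not in X.columns]
        if missing:
            raise KeyError(f"marker column(s) missing from X: {missing}")
        mat = X[markers].to_numpy(dtype=float)
    else:
        mat = np.atleast_2d(np.asarray(X, dtype=float))
        if mat.shape[1] != len(markers):
            raise ValueError("X width does not match the number of coefficients")
    beta = np.array([model.coefficients[m] for m in markers])
    eta = model.intercept + mat @ beta
    return 1.0 / (1.0 + np.exp(-eta))


def in_sample_metrics(model: LogisticPanelModel, X, labels: GroupLabels,
                      cutoff: float = 0.5) -> ClassificationMetrics:
    """Training-data confusion metrics, classifying case iff prob >= cutoff."""
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must be in (0, 1)")
    probs = predict_proba(model, X)
    return ClassificationMetrics.from_predictions(
        labels.status, (probs >= cutoff).astype(int), cutoff
    )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _lambda_path(X: np.ndarray, y: np.ndarray, n_lambdas: int,
                 min_ratio: float) -> np.ndarray:
    # smallest lambda killing every coefficient, glmnet-style
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def _deviance(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    probs = np.clip(probs, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(probs) + (1 - y) * np.log(1 - probs)))


class LassoPanelLogistic(ClassifierMixin, BaseEstimator):
    """L1-penalized logistic panel selector/classifier (scikit-learn style).

    Expects standardized features (it never re-standardizes internally).

    Parameters
    ----------
    lambda_strategy : str, default="cv"
        ``"cv"``, ``"support_size:K"`` or ``"fixed:V"`` (see module docs).
    n_folds : int, default=10
        Folds for the ``"cv"`` strategy (stratified, shuffled by seed).
    n_lambdas : int, default=50
        Path length for ``"cv"`` and ``"support_size"``.
    lambda_min_ratio : float, default=1e-2
        Smallest path lambda relative to the all-zero lambda (with the
        screened set comparable in size to n, pushing the path further
        toward the unpenalized fit mostly explores near-separable models).
    coef_tol : float, default=1e-8
        Zero threshold for the support.
    random_state : int, default=0
        Seeds the cross-validation fold shuffling.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (p,)
    lambda_ : float
    support_ : list of str, markers with |beta| > coef_tol
    marker_auc_ : dict, per-marker empirical AUC on the training data
    separation_flag_ : bool, raised for a separated unpenalized fit
    cv_path_ : DataFrame (cv strategy only): lambda, mean held-out deviance
    """

    def __init__(self, lambda_strategy: str = "cv", n_folds: int = 10,
                 n_lambdas: int = 50, lambda_min_ratio: float = 1e-2,
                 coef_tol: float = DEFAULT_COEF_TOL, max_iter: int = 20000,
                 random_state: int = 0):
        self.lambda_strategy = lambda_strategy
        self.n_folds = n_folds
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.coef_tol = coef_tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _fit_at(self, X: np.ndarray, y: np.ndarray, lam: float,
                warm: tuple[float, np.ndarray] | None = None
                ) -> tuple[float, np.ndarray]:
        if lam == 0:
            est = LogisticRegression(C=np.inf, solver="lbfgs",
                                     tol=1e-10, max_iter=self.max_iter)
            est.fit(X, y)
            return float(est.intercept_[0]), est.coef_[0].copy()
        b0_init, beta_init = warm if warm is not None else (None, None)
        b0, beta, _ = fit_l1_logistic(X, y, lam, beta0_init=b0_init,
                                      beta_init=beta_init)
        return b0, beta

    def _resolve_lambda(self, X: np.ndarray, y: np.ndarray) -> float:
        strategy = self.lambda_strategy
        if strategy == "cv":
            return self._cv_lambda(X, y)
        if strategy.startswith("support_size:"):
            k = int(strategy.split(":", 1)[1])
            return self._support_size_lambda(X, y, k)
        if strategy.startswith("fixed:"):
            lam = float(strategy.split(":", 1)[1])
            if lam < 0:
                raise ValueError("fixed lambda must be >= 0")
            return lam
        raise ValueError(f"unknown lambda_strategy {strategy!r}")

    def _path_fits(self, X: np.ndarray, y: np.ndarray, lams: np.ndarray):
        """Warm-started L1 path, largest lambda first."""
        out = []
        warm = None
        for lam in lams:
            warm = self._fit_at(X, y, lam, warm=warm)
            out.append((warm[0], warm[1].copy()))
        return out

    def _cv_lambda(self, X: np.ndarray, y: np.ndarray) -> float:
        lams = _lambda_path(X, y, self.n_lambdas, self.lambda_min_ratio)
        n_folds = min(self.n_folds, int(y.sum()), int((1 - y).sum()))
        if n_folds < 2:
            raise ValueError("too few subjects per class for cross-validation")
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=self.random_state)
        dev = np.zeros((len(lams), n_folds))
        for f, (tr, te) in enumerate(skf.split(X, y)):
            for i, (b0, beta) in enumerate(self._path_fits(X[tr], y[tr], lams)):
                probs = 1.0 / (1.0 + np.exp(-(b0 + X[te] @ beta)))
                dev[i, f] = _deviance(probs, y[te]) / len(te)
        mean_dev = dev.mean(axis=1)
        # ties to the largest lambda (sparser model); path is descending
        best = int(np.argmin(mean_dev))
        self.cv_path_ = pd.DataFrame({"lambda": lams, "mean_deviance": mean_dev})
        return float(lams[best])

    def _support_size_lambda(self, X: np.ndarray, y: np.ndarray, k: int) -> float:
        if k < 0:
            raise ValueError("support size must be >= 0")
        lams = _lambda_path(X, y, self.n_lambdas, self.lambda_min_ratio)
        for lam, (_, beta) in zip(lams, self._path_fits(X, y, lams)):
            # descending path: the first hit is the largest such lambda
            if int((np.abs(beta) > self.coef_tol).sum()) == k:
                return float(lam)
        raise ValueError(f"no lambda on the path yields a support of size {k}")

    def fit(self, X, y):
        mat, marker_ids = _as_matrix(X)
        y_arr = np.asarray(
            y.status if isinstance(y, GroupLabels) else y, dtype=float
        )
        if mat.shape[0] != len(y_arr):
            raise ValueError("X and y differ in length")
        if len(y_arr) < 4:
            raise ValueError("need n >= 4 subjects")
        if set(np.unique(y_arr)) != {0.0, 1.0}:
            raise ValueError("y must contain both classes, coded 0/1")
        if np.isnan(mat).any():
            raise ValueError("X contains missing values")

        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(marker_ids, dtype=object)
        self.n_features_in_ = len(marker_ids)
        self.lambda_ = self._resolve_lambda(mat, y_arr)
        self.intercept_, self.coef_ = self._fit_at(mat, y_arr, self.lambda_)

        self.separation_flag_ = False
        if self.lambda_ == 0:
            scores = self.intercept_ + mat @ self.coef_
            sep = scores[y_arr == 1].min() > scores[y_arr == 0].max()
            if sep and np.max(np.abs(self.coef_), initial=0.0) > 10:
                self.separation_flag_ = True

        self.marker_auc_ = {
            m: empirical_auc(mat[:, j], y_arr.astype(int))
            for j, m in enumerate(marker_ids)
        }
        self.support_ = nonzero_support(self.to_panel_model(), self.coef_tol)
        return self

    def to_panel_model(self) -> LogisticPanelModel:
        check_is_fitted(self, "coef_")
        return LogisticPanelModel(
            intercept=self.intercept_,
            coefficients={m: float(b) for m, b
                          in zip(self.feature_names_in_, self.coef_)},
            lam=self.lambda_,
            fit_meta={
                "lambda_strategy": self.lambda_strategy,
                "separation": self.separation_flag_,
                "random_state": self.random_state,
            },
            marker_auc=dict(self.marker_auc_),
        )

    def predict_proba(self, X):
        check_is_fitted(self, "coef_")
        mat, _ = _as_matrix(X)
        p1 = 1.0 / (1.0 + np.exp(-(self.intercept_ + mat @ self.coef_)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def fit_lasso_logistic(X, y, lambda_strategy: str = "cv", seed: int = 0,
                       **kwargs) -> LogisticPanelModel:
    """Functional wrapper over :class:`LassoPanelLogistic`."""
    est = LassoPanelLogistic(lambda_strategy=lambda_strategy,
                             random_state=seed, **kwargs)
    est.fit(X, y)
    return est.to_panel_model()


@dataclass
class StepAicResult:
    final_support: list[str]
    model: LogisticPanelModel
    trace: list[dict]
    ridged: bool = False


def step_aic_refine(X: pd.DataFrame, y, support: list[str],
                    ridge_fallback: float = 1e-6) -> StepAicResult:
    """Backward elimination from ``support`` under AIC.

    Each candidate removal refits the unpenalized logistic model; the
    removal lowering AIC the most is applied, until none lowers it.
    Separated candidate fits fall back to a flagged tiny-ridge refit.
    Deterministic: AIC ties break toward the earlier marker in ``support``.
    """
    if not support:
        raise ValueError("support must be nonempty")
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with marker columns")
    missing = [m for m in support if m not in X.columns]
    if missing:
        raise KeyError(f"support marker(s) absent from X: {missing}")
    y_arr = np.asarray(y.status if isinstance(y, GroupLabels) else y, dtype=float)

    any_ridged = False

    def _fit(markers: list[str]):
        mat = X[markers].to_numpy(dtype=float) if markers else np.empty((len(X), 0))
        return fit_logistic(mat, y_arr, ridge_fallback=ridge_fallback)

    current = list(support)
    fit = _fit(current)
    any_ridged |= fit.ridged
    current_aic = aic(fit.llf, len(current))
    trace = [{"support_size": len(current), "aic": current_aic, "removed": None}]

    while current:
        candidates = []
        for m in current:
            reduced = [x for x in current if x != m]
            cfit = _fit(reduced)
            candidates.append((aic(cfit.llf, len(reduced)), m, reduced, cfit))
        best_aic, removed, reduced, best_fit = min(
            candidates, key=lambda c: (c[0], support.index(c[1]))
        )
        if best_aic >= current_aic - 1e-12:
            break
        any_ridged |= best_fit.ridged
        current, current_aic, fit = reduced, best_aic, best_fit
        trace.append({"support_size": len(current), "aic": current_aic,
                      "removed": removed})

    model = LogisticPanelModel(
        intercept=fit.intercept,
        coefficients={m: float(b) for m, b in zip(current, fit.coef)},
        lam=0.0,
        fit_meta={"method": "step_aic_backward", "ridged": any_ridged,
                  "aic": current_aic},
    )
    return StepAicResult(final_support=current, model=model, trace=trace,
                         ridged=any_ridged)


def panel_table(lasso_model: LogisticPanelModel, final_support: list[str],
                tol: float = DEFAULT_COEF_TOL) -> pd.DataFrame:
    """Panel summary: coefficient, odds-ratio factor, membership flags."""
    support = set(nonzero_support(lasso_model, tol))
    final = set(final_support)
    rows = []
    for m, b in lasso_model.coefficients.items():
        rows.append({
            "marker_id": m,
            "coefficient": b,
            "odds_ratio_factor": odds_ratio_factor(b),
            "in_lasso_support": int(m in support),
            "in_final_panel": int(m in final),
        })
    return pd.DataFrame(rows)
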