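"""Shared penalized-regression machinery.

All soil-scale models in this package are intercept-free linear models with
non-negative coefficients, fitted by Lasso or Ridge with the penalty strength
selected by seeded K-fold cross-validation.  Predictors are scaled by their
standard deviation before fitting (no centering, which would destroy the
intercept-free structure) and coefficients are back-transformed, so reported
lambda values live on the scaled-predictor scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold

__all__ = ["PenalizedFit", "fit_penalized", "lambda_grid", "nnls_fit"]


@dataclass
class PenalizedFit:
    """Result of a penalized, non-negative, intercept-free linear fit."""

    names: list[str]
    coefficients: np.ndarray
    std_coefficients: np.ndarray  # coef * sd(x) / sd(y)
    penalty: str
    lambda_optimal: float
    r2: float
    r2_adj: float
    cv_folds: int
    seed: int
    dropped: list[str] = field(default_factory=list)  # zero-variance predictors

    @property
    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.coefficients.tolist()))

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(np.abs(self.coefficients) > 0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients


def nnls_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Non-negative least squares (the lambda = 0 limit of both penalties)."""
    coef, _ = nnls(np.asarray(X, dtype=float), np.asarray(y, dtype=float))
    return coef


def lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int = 100) -> np.ndarray:
    """Log-spaced penalty grid with a data-driven maximum.

    The maximum is the smallest Lasso lambda that zeroes every coefficient,
    max|X'y|/n; the minimum is 1e-4 times that, and lambda = 0 (the
    unpenalized non-negative fit) is always included so cross-validation can
    select no shrinkage at all.  The same grid is used for Ridge, where it
    simply brackets the useful shrinkage range.
    """
    n = X.shape[0]
    lam_max = float(np.max(np.abs(X.T @ y)) / n)
    if lam_max <= 0:
        lam_max = 1.0
    return np.concatenate([[0.0], np.geomspace(lam_max * 1e-4, lam_max, n_lambdas - 1)])


def _solve(X: np.ndarray, y: np.ndarray, penalty: str, lam: float) -> np.ndarray:
    if lam <= 0:
        return nnls_fit(X, y)
    cls = Lasso if penalty == "lasso" else Ridge
    model = cls(alpha=lam, positive=True, fit_intercept=False, max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return np.asarray(model.coef_, dtype=float)


def fit_penalized(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    penalty: str = "lasso",
    cv: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 100,
) -> PenalizedFit:
    """Non-negative, intercept-free Lasso/Ridge with CV-selected penalty.

    Fold assignment is a seeded shuffle.  The adjusted R2 uses the number of
    nonzero coefficients as the effective parameter count:
    R2_adj = 1 - (1 - R2)(n - 1)/(n - p - 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per observation in y")
    if penalty not in ("lasso", "ridge"):
        raise ValueError(f"penalty must be 'lasso' or 'ridge', got {penalty!r}")
    n = X.shape[0]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)

    # Drop zero-variance predictors with a warning.
    scales = X.std(axis=0, ddof=1) if n > 1 else np.abs(X).max(axis=0)
    keep = scales > 0
    dropped = [nm for nm, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance predictors: {dropped}", stacklevel=2)
    Xk = X[:, keep]
    kept_names = [nm for nm, k in zip(names, keep) if k]
    sk = scales[keep]

    full_coef = np.zeros(len(names))
    if Xk.shape[1] == 0 or not np.any(y != 0):
        # Nothing to fit (no usable predictors, or an identically-zero target
        # for which the non-negative zero vector is already optimal).
        r2 = 1.0 if not np.any(y != 0) else 0.0
        return PenalizedFit(
            names=names,
            coefficients=full_coef,
            std_coefficients=np.zeros(len(names)),
            penalty=penalty,
            lambda_optimal=0.0,
            r2=r2,
            r2_adj=r2,
            cv_folds=cv,
            seed=seed,
            dropped=dropped,
        )

    Xs = Xk / sk
    if lambdas is None:
        lambdas = lambda_grid(Xs, y, n_lambdas)
    lambdas = np.asarray(lambdas, dtype=float)

    n_splits = min(cv, n)
    if n_splits >= 2:
        kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
        cv_mse = np.zeros(len(lambdas))
        for train, test in kf.split(Xs):
            for i, lam in enumerate(lambdas):
                coef = _solve(Xs[train], y[train], penalty, lam)
                resid = y[test] - Xs[test] @ coef
                cv_mse[i] += float(resid @ resid)
        best = int(np.argmin(cv_mse))
        lam_opt = float(lambdas[best])
    else:
        lam_opt = float(lambdas[0])

    coef_s = _solve(Xs, y, penalty, lam_opt)
    coef = coef_s / sk

    yhat = Xk @ coef
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    p = int(np.sum(np.abs(coef) > 0))
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else float("nan")

    sy = y.std(ddof=1) if n > 1 else 0.0
    std_coef_k = coef * sk / sy if sy > 0 else np.zeros_like(coef)

    full_coef[keep] = coef
    full_std = np.zeros(len(names))
    full_std[keep] = std_coef_k
    return PenalizedFit(
        names=names,
        coefficients=full_coef,
        std_coefficients=full_std,
        penalty=penalty,
        lambda_optimal=lam_opt,
        r2=r2,
        r2_adj=r2_adj,
        cv_folds=n_splits,
        seed=seed,
        dropped=dropped,
    )
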