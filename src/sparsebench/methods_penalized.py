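"""Frequentist penalized estimators: LASSO, elastic net, adaptive LASSO.

All three select their penalty by 10-fold cross-validation at the
CV-error-minimizing lambda (the ``lambda.min`` rule).  Solutions come from
scikit-learn's coordinate descent, which produces exact zeros; the penalty
grid is 100 log-spaced values from lambda_max (smallest penalty with an
all-zero solution) down to 1e-4 * lambda_max.

Conventions: inputs are standardized (columns mean 0 / sd 1, response
centered).  The objective is (1/2n)||y - X b||^2 + lam * pen(b), matching
scikit-learn's ``alpha`` scale.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV, Lasso, LassoCV, RidgeCV
from sklearn.model_selection import KFold

from .base import MethodResult

__all__ = ["PenaltyConfig", "fit_lasso", "fit_elastic_net", "fit_alasso", "lasso_at"]

#: cap on adaptive weights when a ridge coefficient is exactly zero
MAX_ADAPTIVE_WEIGHT = 1e8


@dataclass
class PenaltyConfig:
    alpha_mix: float = 1.0
    n_folds: int = 10
    lambda_grid: np.ndarray | None = None
    weights: np.ndarray | None = None
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_mix <= 1.0:
            raise ValueError("alpha_mix must lie in [0, 1]")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(g <= 0) or np.any(np.diff(g) >= 0):
                raise ValueError("lambda_grid must be strictly positive and decreasing")
            self.lambda_grid = g
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w <= 0):
                raise ValueError("weights must be strictly positive")
            self.weights = w


def lambda_grid(X: np.ndarray, y: np.ndarray, cfg: PenaltyConfig) -> np.ndarray:
    """Decreasing penalty grid from lambda_max down to ratio * lambda_max.

    lambda_max = max |X^T y| / (n * mix) is the smallest penalty whose
    solution is identically zero (for mix > 0).
    """
    if cfg.lambda_grid is not None:
        return cfg.lambda_grid
    n = X.shape[0]
    mix = max(cfg.alpha_mix, 1e-3)
    lam_max = np.max(np.abs(X.T @ y)) / (n * mix)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, cfg.lambda_min_ratio * lam_max, cfg.n_lambda)


def _cv_splitter(n: int, cfg: PenaltyConfig, rng: np.random.Generator | None) -> KFold:
    if n < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} rows for {cfg.n_folds}-fold CV, got {n}")
    seed = int(rng.integers(2**31 - 1)) if rng is not None else 0
    return KFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)


def fit_lasso(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PenaltyConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MethodResult:
    """l1-penalized least squares with CV-chosen penalty."""
    cfg = cfg or PenaltyConfig(alpha_mix=1.0)
    t0 = time.perf_counter()
    grid = lambda_grid(X, y, cfg)
    model = LassoCV(alphas=grid, cv=_cv_splitter(len(y), cfg, rng), fit_intercept=False)
    model.fit(X, y)
    # tight refit at the chosen penalty so the KKT conditions hold to ~1e-8
    beta = lasso_at(X, y, float(model.alpha_))
    return MethodResult(
        method_name="LASSO",
        beta_hat=beta,
        hyperparams={"lambda": float(model.alpha_)},
        runtime_s=time.perf_counter() - t0,
    )


def fit_elastic_net(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PenaltyConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MethodResult:
    """Elastic net: penalty mix * l1 + (1 - mix)/2 * l2, mix = 0.5 by default."""
    cfg = cfg or PenaltyConfig(alpha_mix=0.5)
    if cfg.alpha_mix == 1.0:
        res = fit_lasso(X, y, cfg, rng)
        res.method_name = "EL"
        return res
    t0 = time.perf_counter()
    grid = lambda_grid(X, y, cfg)
    model = ElasticNetCV(
        alphas=grid, l1_ratio=cfg.alpha_mix, cv=_cv_splitter(len(y), cfg, rng), fit_intercept=False
    )
    model.fit(X, y)
    beta = lasso_at(X, y, float(model.alpha_), alpha_mix=cfg.alpha_mix)
    return MethodResult(
        method_name="EL",
        beta_hat=beta,
        hyperparams={"lambda": float(model.alpha_), "alpha_mix": cfg.alpha_mix},
        runtime_s=time.perf_counter() - t0,
    )


def fit_alasso(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PenaltyConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MethodResult:
    """Adaptive LASSO: ridge-initialized weights w_j = 1/|b_init_j|, then a
    weighted l1 fit with its own CV-chosen penalty.

    The weighted problem is solved by rescaling columns X_j -> X_j / w_j,
    running a plain LASSO, and mapping coefficients back.
    """
    cfg = cfg or PenaltyConfig(alpha_mix=1.0)
    t0 = time.perf_counter()
    if cfg.weights is not None:
        w = cfg.weights
        ridge_alpha = None
    else:
        ridge = RidgeCV(alphas=np.geomspace(1e-3, 1e4, 50), cv=_cv_splitter(len(y), cfg, rng))
        ridge.fit(X, y)
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0 / np.abs(ridge.coef_), MAX_ADAPTIVE_WEIGHT)
        ridge_alpha = float(ridge.alpha_)
    Xw = X / w
    grid = lambda_grid(Xw, y, cfg)
    model = LassoCV(alphas=grid, cv=_cv_splitter(len(y), cfg, rng), fit_intercept=False)
    model.fit(Xw, y)
    beta = lasso_at(Xw, y, float(model.alpha_)) / w
    hyper = {"lambda": float(model.alpha_), "weights_max": float(np.max(w))}
    if ridge_alpha is not None:
        hyper["ridge_lambda"] = ridge_alpha
    return MethodResult(
        method_name="ALASSO",
        beta_hat=beta,
        hyperparams=hyper,
        runtime_s=time.perf_counter() - t0,
    )


def lasso_at(X: np.ndarray, y: np.ndarray, lam: float, alpha_mix: float = 1.0) -> np.ndarray:
    """Solution at a fixed penalty (no CV); used for oracle checks."""
    cls = Lasso if alpha_mix == 1.0 else ElasticNet
    kw = {} if alpha_mix == 1.0 else {"l1_ratio": alpha_mix}
    model = cls(alpha=lam, fit_intercept=False, tol=1e-10, max_iter=100000, **kw)
    model.fit(X, y)
    return model.coef_
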