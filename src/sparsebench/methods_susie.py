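"""Sum of Single Effects regression fitted by Iterative Bayesian Stepwise
Selection (IBSS).

The coefficient vector is modelled as a sum of L "single effects"
``beta = sum_l gamma_l g_l`` where each ``gamma_l`` is a one-hot indicator
with categorical prior ``pi`` and ``g_l ~ N(0, tau_l^2)``.  IBSS cyclically
fits each single-effect regression (SER) to the residual that excludes that
effect's current fitted contribution; the prior effect variances ``tau_l^2``
are re-estimated per effect by empirical Bayes (maximizing the SER marginal
likelihood) and the residual variance by the expected-residual-sum-of-squares
update.  Per-feature posterior inclusion probabilities combine across
effects as ``pip_j = 1 - prod_l (1 - alpha_lj)``.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .base import MethodResult

__all__ = ["SusieModel", "fit_ser", "fit_susie", "ser_log_marginal"]


@dataclass
class SusieModel:
    L: int
    alpha: np.ndarray  # L x p, rows sum to 1
    mu: np.ndarray  # L x p posterior means of g_l given inclusion
    mu2: np.ndarray  # L x p posterior second moments given inclusion
    tau2: np.ndarray  # length L prior effect variances
    pi0: np.ndarray  # length p prior weights
    sigma2: float
    elbo_trace: list = field(default_factory=list)
    converged: bool = True

    @property
    def pip(self) -> np.ndarray:
        return 1.0 - np.prod(1.0 - self.alpha, axis=0)

    @property
    def coef(self) -> np.ndarray:
        """Posterior mean of beta: sum over effects of alpha * mu."""
        return np.sum(self.alpha * self.mu, axis=0)


def _ser_sufficient(X: np.ndarray, y: np.ndarray, sigma2: float):
    xtx = np.einsum("ij,ij->j", X, X)
    xtx = np.maximum(xtx, 1e-12)
    bhat = (X.T @ y) / xtx
    s2 = sigma2 / xtx
    return bhat, s2


def ser_log_marginal(tau2: float, bhat: np.ndarray, s2: np.ndarray, pi0: np.ndarray) -> float:
    """Log marginal likelihood of the SER model (up to the common constant
    from the null model): log sum_j pi_j BF_j."""
    log_bf = 0.5 * (
        np.log(s2 / (s2 + tau2)) + bhat**2 * tau2 / (s2 * (s2 + tau2))
    )
    m = np.max(log_bf)
    return float(m + np.log(np.sum(pi0 * np.exp(log_bf - m))))


def fit_ser(
    X: np.ndarray,
    y: np.ndarray,
    tau2: float,
    sigma2: float,
    pi0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-effect regression: exact posterior over which single feature
    carries the effect.

    Returns (alpha, mu, mu2): the per-feature inclusion posterior
    (normalized pi_j * BF_j), and the posterior mean / second moment of the
    effect size given inclusion.
    """
    p = X.shape[1]
    pi0 = np.full(p, 1.0 / p) if pi0 is None else np.asarray(pi0, dtype=float)
    bhat, s2 = _ser_sufficient(X, y, sigma2)
    log_bf = 0.5 * (np.log(s2 / (s2 + tau2)) + bhat**2 * tau2 / (s2 * (s2 + tau2)))
    with np.errstate(divide="ignore"):
        log_w = np.log(pi0) + log_bf
    if not np.any(np.isfinite(log_w)):
        raise RuntimeError("all single-effect Bayes factors are non-finite")
    log_w -= np.max(log_w[np.isfinite(log_w)])
    w = np.exp(log_w)
    alpha = w / w.sum()
    post_var = tau2 * s2 / (tau2 + s2)
    mu = post_var * bhat / s2
    mu2 = post_var + mu**2
    return alpha, mu, mu2


def _estimate_tau2(bhat, s2, pi0, tau2_init: float) -> float:
    """Empirical-Bayes prior variance for one effect: maximize the SER
    marginal likelihood over tau^2 (on the log scale)."""

    def neg(log_t):
        return -ser_log_marginal(np.exp(log_t), bhat, s2, pi0)

    x0 = np.log(max(tau2_init, 1e-8))
    res = minimize_scalar(neg, bracket=(x0 - 2, x0, x0 + 2) if False else None,
                          bounds=(-20.0, 10.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(np.exp(res.x))


def _elbo(X, y, model: SusieModel, xtx) -> float:
    """Variational lower bound under the current posterior approximation."""
    n = len(y)
    sigma2 = model.sigma2
    erss = _erss(X, y, model, xtx)
    fit_term = -0.5 * n * np.log(2 * np.pi * sigma2) - erss / (2 * sigma2)
    kl = 0.0
    for l in range(model.L):
        a, mu, mu2, t2 = model.alpha[l], model.mu[l], model.mu2[l], model.tau2[l]
        s2_post = np.maximum(mu2 - mu**2, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_ratio = np.where(a > 0, np.log(np.maximum(a, 1e-300) / model.pi0), 0.0)
        kl_gauss = 0.5 * (np.log(t2 / s2_post) + (mu2) / t2 - 1.0)
        kl += float(np.sum(a * (log_ratio + kl_gauss)))
    return float(fit_term - kl)


def _erss(X, y, model: SusieModel, xtx) -> float:
    """Expected residual sum of squares under the factorized posterior."""
    bbar_l = model.alpha * model.mu  # L x p
    fitted = X @ bbar_l.sum(axis=0)
    erss = float(np.sum((y - fitted) ** 2))
    for l in range(model.L):
        xb_l = X @ bbar_l[l]
        erss -= float(xb_l @ xb_l)
        erss += float(np.sum(xtx * model.alpha[l] * model.mu2[l]))
    return erss


def fit_susie(
    X: np.ndarray,
    y: np.ndarray,
    L: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    estimate_tau2: bool = True,
    estimate_sigma2: bool = True,
    tau2_init: float = 0.2,
    pi0: np.ndarray | None = None,
) -> MethodResult:
    """IBSS fit of the sum-of-single-effects model with L effects."""
    if L < 1:
        raise ValueError("L must be >= 1")
    t0 = time.perf_counter()
    n, p = X.shape
    pi0 = np.full(p, 1.0 / p) if pi0 is None else np.asarray(pi0, dtype=float)
    xtx = np.maximum(np.einsum("ij,ij->j", X, X), 1e-12)
    model = SusieModel(
        L=L,
        alpha=np.full((L, p), 1.0 / p),
        mu=np.zeros((L, p)),
        mu2=np.zeros((L, p)),
        tau2=np.full(L, tau2_init),
        pi0=pi0,
        sigma2=float(np.var(y)) if estimate_sigma2 else 1.0,
    )
    model.mu2 = model.mu**2
    fitted = np.zeros(n)
    contrib = np.zeros((L, n))
    converged = False
    for _it in range(max_iter):
        fitted_old = fitted.copy()
        for l in range(L):
            r_l = y - (fitted - contrib[l])
            bhat, s2 = _ser_sufficient(X, r_l, model.sigma2)
            if estimate_tau2:
                model.tau2[l] = _estimate_tau2(bhat, s2, pi0, model.tau2[l])
            alpha, mu, mu2 = fit_ser(X, r_l, model.tau2[l], model.sigma2, pi0)
            model.alpha[l], model.mu[l], model.mu2[l] = alpha, mu, mu2
            new_contrib = X @ (alpha * mu)
            fitted += new_contrib - contrib[l]
            contrib[l] = new_contrib
        if estimate_sigma2:
            model.sigma2 = max(_erss(X, y, model, xtx) / n, 1e-12)
        model.elbo_trace.append(_elbo(X, y, model, xtx))
        if np.max(np.abs(fitted - fitted_old)) < tol:
            converged = True
            break
    model.converged = converged
    if not converged:
        warnings.warn("IBSS did not converge within max_iter", RuntimeWarning)
    pip = model.pip
    return MethodResult(
        method_name="SUSIE",
        beta_hat=model.coef,
        pip=pip,
        posterior_mean=model.coef,
        hyperparams={"L": L, "tau2": model.tau2.copy(), "sigma2": model.sigma2,
                     "model": model},
        runtime_s=time.perf_counter() - t0,
        selection_carrier="pip",
        converged=converged,
    )
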