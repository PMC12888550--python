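"""Mixture-prior selectors.

SSVS ("SN"): normal spike-and-slab with latent Bernoulli inclusion
indicators.  Each coefficient has prior sd ``spike_sd`` (inactive) or
``slab_sd`` (active); the Gibbs chain alternates a joint Gaussian draw of
beta given the indicators, coordinate-wise Bernoulli flips of the indicators
given beta, and a conjugate inverse-gamma draw of sigma^2.  Posterior
inclusion probabilities are the post-burn-in indicator means.

SSLASSO: spike-and-slab LASSO, a deterministic coordinate-ascent solver for
the Laplace-mixture prior.  The non-separable penalty is handled by
majorization: each coordinate is soft-thresholded at the adaptive level
``lam*(b_j) = lam1 p*(b_j) + lam0 (1 - p*(b_j))`` where ``p*`` is the
conditional probability that the coefficient came from the slab.  Solutions
are warm-started along an increasing spike-penalty grid; the returned fit is
the converged grid point with minimal OLS-refit BIC (ties to the largest
spike penalty).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .base import MethodResult
from .methods_bayes import McmcConfig, _inv_gamma, draw_coefficients

__all__ = [
    "SpikeSlabConfig",
    "SslassoConfig",
    "fit_ssvs",
    "fit_sslasso",
    "ssvs_step",
    "ssvs_prior_draw",
    "indicator_log_odds",
    "sslasso_objective",
]

#: consecutive zero-flip sweeps before a stuck-chain warning
STUCK_WINDOW = 500


@dataclass
class SpikeSlabConfig:
    omega: float = 0.5
    spike_sd: float = 0.01
    slab_sd: float = 1.0
    sigma2_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0.0 < self.omega < 1.0:
            raise ValueError("omega must lie in (0, 1)")
        if self.spike_sd > 0.01 * self.slab_sd:
            raise ValueError("spike_sd must be << slab_sd (ratio <= 0.01)")


@dataclass
class SslassoConfig:
    lambda1: float = 0.1
    lambda0_grid: np.ndarray | None = None
    theta_prior: tuple[float, float] = (1.0, 1.0)
    max_sweeps: int = 500
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.lambda0_grid is None:
            self.lambda0_grid = np.geomspace(self.lambda1, 100.0, 10)
        g = np.asarray(self.lambda0_grid, dtype=float)
        if np.any(np.diff(g) < 0) or np.any(g < self.lambda1):
            raise ValueError("lambda0_grid must be increasing and >= lambda1")
        self.lambda0_grid = g


def indicator_log_odds(beta: np.ndarray, omega: float, spike_sd: float, slab_sd: float):
    """Closed-form log odds of inclusion given the coefficient value:
    log[ omega N(b; 0, c^2) ] - log[ (1-omega) N(b; 0, eps^2) ]."""
    b2 = np.asarray(beta, dtype=float) ** 2
    return (
        np.log(omega / (1.0 - omega))
        + np.log(spike_sd / slab_sd)
        + 0.5 * b2 * (1.0 / spike_sd**2 - 1.0 / slab_sd**2)
    )


def ssvs_prior_draw(
    p: int, cfg: SpikeSlabConfig, rng: np.random.Generator,
    sigma2_fixed: float | None = None,
):
    """(beta, gamma, sigma2) drawn from the spike-and-slab prior."""
    gamma = rng.random(p) < cfg.omega
    sd = np.where(gamma, cfg.slab_sd, cfg.spike_sd)
    beta = rng.standard_normal(p) * sd
    if sigma2_fixed is not None:
        sigma2 = float(sigma2_fixed)
    else:
        a0, b0 = cfg.sigma2_prior
        sigma2 = float(_inv_gamma(a0, b0, rng))
    return beta, gamma, sigma2


def ssvs_step(
    beta: np.ndarray,
    gamma: np.ndarray,
    sigma2: float,
    X: np.ndarray,
    y: np.ndarray,
    cfg: SpikeSlabConfig,
    rng: np.random.Generator,
    sigma2_fixed: float | None = None,
):
    """One Gibbs scan: beta | gamma (joint Gaussian), gamma | beta
    (coordinate Bernoulli flips), sigma^2 | beta (inverse-gamma).
    Returns (beta, gamma, sigma2, n_flips)."""
    n = X.shape[0]
    prior_var = np.where(gamma, cfg.slab_sd**2, cfg.spike_sd**2)
    beta = draw_coefficients(X, y, prior_var, sigma2, rng)
    log_odds = indicator_log_odds(beta, cfg.omega, cfg.spike_sd, cfg.slab_sd)
    prob = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
    new_gamma = rng.random(len(beta)) < prob
    n_flips = int(np.sum(new_gamma != gamma))
    if sigma2_fixed is None:
        a0, b0 = cfg.sigma2_prior
        rss = float(np.sum((y - X @ beta) ** 2))
        sigma2 = float(_inv_gamma(a0 + n / 2.0, b0 + rss / 2.0, rng))
    else:
        sigma2 = float(sigma2_fixed)
    return beta, new_gamma, sigma2, n_flips


def fit_ssvs(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SpikeSlabConfig,
    mcmc: McmcConfig,
    sigma2_fixed: float | None = None,
) -> MethodResult:
    """Stochastic search variable selection with normal spike and slab."""
    t0 = time.perf_counter()
    n, p = X.shape
    rng = np.random.default_rng(mcmc.seed)
    gamma = rng.random(p) < cfg.omega
    sigma2 = float(sigma2_fixed) if sigma2_fixed is not None else 1.0
    beta = np.zeros(p)
    pip_total = np.zeros(p)
    beta_total = np.zeros(p)
    kept = 0
    stuck = 0
    warned = False
    for it in range(mcmc.n_iter):
        beta, gamma, sigma2, n_flips = ssvs_step(
            beta, gamma, sigma2, X, y, cfg, rng, sigma2_fixed
        )
        stuck = stuck + 1 if n_flips == 0 else 0
        if stuck >= STUCK_WINDOW and not warned:
            warnings.warn(
                f"SSVS indicators unchanged for {STUCK_WINDOW} consecutive sweeps; "
                "the chain may be stuck (spike too narrow)",
                RuntimeWarning,
            )
            warned = True
        if not np.all(np.isfinite(beta)):
            raise RuntimeError(f"SSVS diverged at iteration {it}")
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            pip_total += gamma
            beta_total += beta
            kept += 1
    pip = pip_total / kept
    post_mean = beta_total / kept
    return MethodResult(
        method_name="SN",
        beta_hat=post_mean,
        pip=pip,
        posterior_mean=post_mean,
        hyperparams={"omega": cfg.omega, "spike_sd": cfg.spike_sd, "slab_sd": cfg.slab_sd},
        runtime_s=time.perf_counter() - t0,
        selection_carrier="pip",
    )


# ---------------------------------------------------------------------------
# SSLASSO


def _pstar(beta: np.ndarray, theta: float, lam0: float, lam1: float) -> np.ndarray:
    """Conditional slab probability p*(b) for the Laplace mixture."""
    # log[(1-theta) lam0 e^{-lam0|b|}] vs log[theta lam1 e^{-lam1|b|}]
    ab = np.abs(beta)
    log_slab = np.log(theta) + np.log(lam1) - lam1 * ab
    log_spike = np.log1p(-theta) + np.log(lam0) - lam0 * ab
    return 1.0 / (1.0 + np.exp(np.clip(log_spike - log_slab, -700, 700)))


def _penalty(beta: np.ndarray, theta: float, lam0: float, lam1: float) -> float:
    ab = np.abs(beta)
    m = np.logaddexp(
        np.log(theta) + np.log(lam1 / 2.0) - lam1 * ab,
        np.log1p(-theta) + np.log(lam0 / 2.0) - lam0 * ab,
    )
    return -float(np.sum(m))


def sslasso_objective(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, theta: float, lam0: float, lam1: float
) -> float:
    """(1/2)||y - X b||^2 - sum_j log[ theta psi_1(b_j) + (1-theta) psi_0(b_j) ]."""
    rss = float(np.sum((y - X @ beta) ** 2))
    return 0.5 * rss + _penalty(beta, theta, lam0, lam1)


def _coordinate_ascent(X, y, beta, theta, lam0, lam1, col_sq, max_sweeps, tol):
    """MM coordinate descent at fixed (theta, lam0).  Returns
    (beta, converged, objective trace)."""
    r = y - X @ beta
    obj = [sslasso_objective(X, y, beta, theta, lam0, lam1)]
    converged = False
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(X.shape[1]):
            bj = beta[j]
            zj = X[:, j] @ r + col_sq[j] * bj
            lam_star = lam1 * _pstar(bj, theta, lam0, lam1) + lam0 * (
                1.0 - _pstar(bj, theta, lam0, lam1)
            )
            new = np.sign(zj) * max(abs(zj) - lam_star, 0.0) / col_sq[j]
            if new != bj:
                r += X[:, j] * (bj - new)
                beta[j] = new
                max_delta = max(max_delta, abs(new - bj))
        obj.append(sslasso_objective(X, y, beta, theta, lam0, lam1))
        if max_delta < tol:
            converged = True
            break
    return beta, converged, obj


def _refit_bic(X, y, selected: np.ndarray) -> float:
    n = len(y)
    k = int(selected.sum())
    if k == 0:
        rss = float(np.sum(y**2))
    else:
        Xs = X[:, selected]
        coef, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        rss = float(np.sum((y - Xs @ coef) ** 2))
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + (k + 1) * np.log(n)


def fit_sslasso(X: np.ndarray, y: np.ndarray, cfg: SslassoConfig | None = None) -> MethodResult:
    """Spike-and-slab LASSO along the spike-penalty grid."""
    cfg = cfg or SslassoConfig()
    t0 = time.perf_counter()
    n, p = X.shape
    a, b = cfg.theta_prior
    col_sq = np.maximum(np.einsum("ij,ij->j", X, X), 1e-12)
    beta = np.zeros(p)
    candidates = []  # (lam0, beta, bic)
    traces = {}
    for lam0 in cfg.lambda0_grid:
        theta = 0.5
        converged = False
        for _outer in range(20):
            # MAP update of the mixing weight theta under its Beta prior
            ps = _pstar(beta, theta, lam0, cfg.lambda1)
            theta = float(np.clip((a - 1.0 + ps.sum()) / (a + b + p - 2.0), 1e-4, 1 - 1e-4)) \
                if a + b + p > 2 else 0.5
            beta, converged, obj = _coordinate_ascent(
                X, y, beta, theta, lam0, cfg.lambda1, col_sq, cfg.max_sweeps, cfg.tol
            )
            if converged:
                break
        traces[float(lam0)] = obj
        if converged:
            selected = beta != 0.0
            candidates.append((float(lam0), beta.copy(), _refit_bic(X, y, selected), theta))
    if not candidates:
        raise RuntimeError(
            f"SSLASSO failed to converge at every grid point: {list(cfg.lambda0_grid)}"
        )
    best_bic = min(c[2] for c in candidates)
    lam0_sel, beta_sel, bic_sel, theta_sel = max(
        (c for c in candidates if c[2] <= best_bic + 1e-9), key=lambda c: c[0]
    )
    return MethodResult(
        method_name="SL",
        beta_hat=beta_sel,
        hyperparams={
            "lambda0": lam0_sel,
            "lambda1": cfg.lambda1,
            "theta": theta_sel,
            "refit_bic": bic_sel,
            "objective_trace": traces[lam0_sel],
        },
        runtime_s=time.perf_counter() - t0,
    )
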