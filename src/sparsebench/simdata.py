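"""Synthetic data generation for the p >> n sparse-regression benchmark.

The generator draws datasets from a linear model ``y = X beta + eps`` under a
grid of study conditions: independent continuous (Normal(0,1)) or binary
(Bernoulli(0.7)) predictors, block-correlated multivariate-normal predictors,
Gaussian or heavy-tailed (Student-t, 2 df) noise, noise either calibrated to a
target signal-to-noise ratio SNR = Var(X beta) / sigma^2 or fixed at a given
sigma, and three coefficient regimes (generic unit-magnitude, ten graded
magnitudes, thirty heterogeneous weak effects).  A nonlinear response design
is included to probe robustness to functional misspecification.

Everything is a pure function of (config, seed): two calls with the same
configuration produce bitwise-identical datasets.

Feature indices are 0-based internally; serialized reports use 1-based
indexing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SimConfig",
    "CoefficientSpec",
    "SimulatedDataset",
    "make_design",
    "make_coefficients",
    "calibrate_noise",
    "make_response",
    "make_nonlinear_dataset",
    "generate",
    "standardize",
    "save_dataset",
    "load_dataset",
]

DESIGNS = ("continuous_indep", "binary_indep", "correlated", "nonlinear")
ERRORS = ("gaussian", "t2")
REGIMES = ("generic", "scenario1", "scenario2")

# Scenario 1: the magnitude multiset {1, 0.5, 0.3, 0.2} cycled to length 10.
SCENARIO1_MAGNITUDES = np.array([1.0, 0.5, 0.3, 0.2] * 2 + [1.0, 0.5])
SCENARIO2_SIZE = 30

_EIG_FLOOR = 1e-6


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated benchmark condition.

    Exactly one of ``snr`` / ``sigma_fixed`` must be set: either the noise
    standard deviation is calibrated so that Var(X beta)/sigma^2 equals
    ``snr`` on the realized training design, or it is fixed at
    ``sigma_fixed`` (the low-noise baseline and Scenario 1/2 regimes).
    """

    n: int = 200
    p: int = 1000
    n_test: int = 50
    sparsity: float = 0.01
    snr: float | None = 1.0
    sigma_fixed: float | None = None
    design: str = "continuous_indep"
    error: str = "gaussian"
    coef_regime: str = "generic"
    rho1: float = 0.3
    rho2: float = 0.5
    rho3: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.sparsity < 1.0:
            raise ValueError(f"sparsity must lie in (0, 1), got {self.sparsity}")
        if (self.snr is None) == (self.sigma_fixed is None):
            raise ValueError("exactly one of snr / sigma_fixed must be set")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.sigma_fixed is not None and self.sigma_fixed <= 0:
            raise ValueError("sigma_fixed must be positive")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.error not in ERRORS:
            raise ValueError(f"unknown error family {self.error!r}")
        if self.coef_regime not in REGIMES:
            raise ValueError(f"unknown coefficient regime {self.coef_regime!r}")
        for name in ("rho1", "rho2", "rho3"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1), got {r}")
        if self.n_test < 1:
            raise ValueError("n_test must be >= 1")
        if self.design == "nonlinear" and self.p < 6:
            raise ValueError("nonlinear design requires p >= 6")
        if self.n < 3:
            raise ValueError("n must be >= 3")


@dataclass(frozen=True)
class CoefficientSpec:
    """True coefficient vector and its support (sorted, 0-based)."""

    beta: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "support", np.asarray(self.support, dtype=int))

    @property
    def n_active(self) -> int:
        return int(self.support.size)


@dataclass(frozen=True)
class SimulatedDataset:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    coef: CoefficientSpec
    sigma: float
    config: SimConfig

    @property
    def support(self) -> np.ndarray:
        return self.coef.support


def _n_active(config: SimConfig) -> int:
    if config.coef_regime == "scenario1":
        return SCENARIO1_MAGNITUDES.size
    if config.coef_regime == "scenario2":
        return SCENARIO2_SIZE
    k = int(round(config.sparsity * config.p))
    if k == 0:
        raise ValueError(
            f"round(sparsity * p) = 0 for sparsity={config.sparsity}, p={config.p}: "
            "no active set"
        )
    return k


def _balanced_signs(k: int, rng: np.random.Generator) -> np.ndarray:
    """Random +-1 vector with |#positive - #negative| <= 1."""
    n_pos = k // 2 + int(k % 2 == 1 and rng.random() < 0.5)
    signs = np.full(k, -1.0)
    signs[rng.choice(k, size=n_pos, replace=False)] = 1.0
    return signs


def make_coefficients(config: SimConfig, rng: np.random.Generator) -> CoefficientSpec:
    """Draw the true coefficient vector for the configured regime.

    generic   : round(s*p) active entries of magnitude 1, balanced signs;
    scenario1 : 10 actives with magnitudes cycled from {1, 0.5, 0.3, 0.2};
    scenario2 : 30 actives with magnitudes uniform on [0.2, 0.7].
    """
    k = _n_active(config)
    support = np.sort(rng.choice(config.p, size=k, replace=False))
    if config.coef_regime == "generic":
        mags = np.ones(k)
    elif config.coef_regime == "scenario1":
        mags = SCENARIO1_MAGNITUDES.copy()
    else:
        mags = rng.uniform(0.2, 0.7, size=k)
    signs = _balanced_signs(k, rng)
    beta = np.zeros(config.p)
    beta[support] = mags * signs
    return CoefficientSpec(beta=beta, support=support)


# Cache of Cholesky factors of the (repaired) block correlation matrix,
# keyed by (p, n_active, rho1, rho2, rho3).  The matrix only depends on the
# block sizes, so datasets permute columns of a canonical draw.
_CHOL_CACHE: dict[tuple, tuple[np.ndarray, float]] = {}


def _block_correlation(k1: int, k2: int, rho1: float, rho2: float, rho3: float) -> np.ndarray:
    p = k1 + k2
    sigma = np.empty((p, p))
    sigma[:k1, :k1] = rho1
    sigma[:k1, k1:] = rho2
    sigma[k1:, :k1] = rho2
    sigma[k1:, k1:] = rho3
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _nearest_pd_correlation(sigma: np.ndarray) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipped positive-definite repair, re-normalized to unit
    diagonal.  Returns (repaired matrix, max entrywise deviation)."""
    w, v = np.linalg.eigh(sigma)
    w_clipped = np.clip(w, _EIG_FLOOR, None)
    repaired = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.max(np.abs(repaired - sigma)))


def _correlated_cholesky(config: SimConfig, k1: int) -> tuple[np.ndarray, float]:
    key = (config.p, k1, config.rho1, config.rho2, config.rho3)
    if key not in _CHOL_CACHE:
        sigma = _block_correlation(k1, config.p - k1, config.rho1, config.rho2, config.rho3)
        deviation = 0.0
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            sigma, deviation = _nearest_pd_correlation(sigma)
            try:
                chol = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    "block correlation matrix not positive definite after repair: "
                    f"rho=({config.rho1}, {config.rho2}, {config.rho3}), "
                    f"block sizes=({k1}, {config.p - k1})"
                ) from None
        _CHOL_CACHE[key] = (chol, deviation)
    return _CHOL_CACHE[key]


def repaired_block_correlation(
    k1: int, k2: int, rho1: float, rho2: float, rho3: float
) -> tuple[np.ndarray, float]:
    """Block correlation matrix after positive-definite repair (if needed),
    with the max entrywise deviation from the target correlations."""
    sigma = _block_correlation(k1, k2, rho1, rho2, rho3)
    if np.linalg.eigvalsh(sigma)[0] > 0:
        return sigma, 0.0
    return _nearest_pd_correlation(sigma)


def make_design(
    config: SimConfig,
    rng: np.random.Generator,
    n_rows: int | None = None,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Draw an (n_rows x p) design matrix from the configured family.

    For the correlated family the active block (``support``, which must
    already be drawn) has within-correlation rho1, the inactive block rho3,
    and rho2 across blocks; an indefinite target matrix is repaired by
    eigenvalue clipping.
    """
    n = config.n if n_rows is None else n_rows
    p = config.p
    if config.design in ("continuous_indep", "nonlinear"):
        return rng.standard_normal((n, p))
    if config.design == "binary_indep":
        return (rng.random((n, p)) < 0.7).astype(float)
    if config.design == "correlated":
        if support is None:
            raise ValueError("correlated design requires the support to be drawn first")
        k1 = len(support)
        chol, _ = _correlated_cholesky(config, k1)
        z = rng.standard_normal((n, p))
        canonical = z @ chol.T
        # canonical columns [0, k1) are the active block; scatter to support
        order = np.empty(p, dtype=int)
        order[np.asarray(support)] = np.arange(k1)
        inactive = np.setdiff1d(np.arange(p), support, assume_unique=True)
        order[inactive] = np.arange(k1, p)
        return canonical[:, order]
    raise ValueError(f"unknown design {config.design!r}")


def calibrate_noise(X: np.ndarray, beta: np.ndarray, snr: float) -> float:
    """Noise sd sigma with sigma^2 = Var(X beta) / snr (sample variance on
    the realized design)."""
    signal = X @ beta
    var = float(np.var(signal, ddof=1))
    if var <= 0.0:
        raise ValueError("X beta has zero variance; SNR calibration undefined")
    return float(np.sqrt(var / snr))


def make_response(
    X: np.ndarray,
    beta: np.ndarray,
    error: str,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """y = X beta + sigma * eps with eps iid N(0,1) or Student-t(2).

    The t2 draws use the same scale multiplier sigma as the Gaussian
    counterpart (t2 has infinite variance, so no variance-matching rescale
    is possible).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n = X.shape[0]
    if error == "gaussian":
        eps = rng.standard_normal(n)
    elif error == "t2":
        eps = rng.standard_t(2, size=n)
    else:
        raise ValueError(f"unknown error family {error!r}")
    return X @ beta + sigma * eps


def nonlinear_mean(X: np.ndarray) -> np.ndarray:
    """Mean response of the nonlinear design:
    sin(pi x1 x2) + x3^2 + log|x4| + (1 - x5) x6."""
    return (
        np.sin(np.pi * X[:, 0] * X[:, 1])
        + X[:, 2] ** 2
        + np.log(np.abs(X[:, 3]))
        + (1.0 - X[:, 4]) * X[:, 5]
    )


def make_nonlinear_dataset(config: SimConfig, rng: np.random.Generator) -> SimulatedDataset:
    """Nonlinear-response dataset; the true support is features 1..6
    (0-based 0..5) and the linear beta is recorded as all-zero."""
    if config.p < 6:
        raise ValueError("nonlinear design requires p >= 6")
    X_all = rng.standard_normal((config.n + config.n_test, config.p))
    X_train, X_test = X_all[: config.n], X_all[config.n :]
    mu_train = nonlinear_mean(X_train)
    mu_test = nonlinear_mean(X_test)
    if config.sigma_fixed is not None:
        sigma = float(config.sigma_fixed)
    else:
        var = float(np.var(mu_train, ddof=1))
        sigma = float(np.sqrt(var / config.snr))
    if config.error == "gaussian":
        eps_tr = rng.standard_normal(config.n)
        eps_te = rng.standard_normal(config.n_test)
    else:
        eps_tr = rng.standard_t(2, size=config.n)
        eps_te = rng.standard_t(2, size=config.n_test)
    coef = CoefficientSpec(beta=np.zeros(config.p), support=np.arange(6))
    return SimulatedDataset(
        X_train=X_train,
        y_train=mu_train + sigma * eps_tr,
        X_test=X_test,
        y_test=mu_test + sigma * eps_te,
        coef=coef,
        sigma=sigma,
        config=config,
    )


def generate(config: SimConfig) -> SimulatedDataset:
    """Generate a full train/test dataset reproducibly from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    if config.design == "nonlinear":
        return make_nonlinear_dataset(config, rng)
    coef = make_coefficients(config, rng)
    X_all = make_design(config, rng, n_rows=config.n + config.n_test, support=coef.support)
    X_train, X_test = X_all[: config.n], X_all[config.n :]
    if config.sigma_fixed is not None:
        sigma = float(config.sigma_fixed)
    else:
        sigma = calibrate_noise(X_train, coef.beta, config.snr)
    y_train = make_response(X_train, coef.beta, config.error, sigma, rng)
    y_test = make_response(X_test, coef.beta, config.error, sigma, rng)
    return SimulatedDataset(
        X_train=X_train,
        y_train=y_train,
        X_test=X_test,
        y_test=y_test,
        coef=coef,
        sigma=sigma,
        config=config,
    )


@dataclass(frozen=True)
class StandardizedData:
    """Train-standardized views of a dataset.

    Train columns are scaled to mean 0 / variance 1 and the same affine map
    is applied to the test block; responses are centered at the train mean.
    All methods consume this representation.
    """

    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float


def standardize(dataset: SimulatedDataset) -> StandardizedData:
    mu = dataset.X_train.mean(axis=0)
    sd = dataset.X_train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    y_mean = float(dataset.y_train.mean())
    return StandardizedData(
        X_train=(dataset.X_train - mu) / sd,
        y_train=dataset.y_train - y_mean,
        X_test=(dataset.X_test - mu) / sd,
        y_test=dataset.y_test - y_mean,
        x_mean=mu,
        x_scale=sd,
        y_mean=y_mean,
    )


def save_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write X/y as CSV plus a JSON sidecar (config, beta, support, sigma).

    The sidecar reports the support 1-based.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "X_train.csv", dataset.X_train, delimiter=",")
    np.savetxt(outdir / "y_train.csv", dataset.y_train, delimiter=",")
    np.savetxt(outdir / "X_test.csv", dataset.X_test, delimiter=",")
    np.savetxt(outdir / "y_test.csv", dataset.y_test, delimiter=",")
    sidecar = {
        "config": dataclasses.asdict(dataset.config),
        "beta": dataset.coef.beta.tolist(),
        "support_1based": (dataset.coef.support + 1).tolist(),
        "sigma": dataset.sigma,
    }
    (outdir / "dataset.json").write_text(json.dumps(sidecar, indent=1))


def load_dataset(indir: str | Path) -> SimulatedDataset:
    indir = Path(indir)
    sidecar = json.loads((indir / "dataset.json").read_text())
    config = SimConfig(**sidecar["config"])
    coef = CoefficientSpec(
        beta=np.array(sidecar["beta"]),
        support=np.array(sidecar["support_1based"], dtype=int) - 1,
    )
    return SimulatedDataset(
        X_train=np.loadtxt(indir / "X_train.csv", delimiter=",", ndmin=2),
        y_train=np.loadtxt(indir / "y_train.csv", delimiter=","),
        X_test=np.loadtxt(indir / "X_test.csv", delimiter=",", ndmin=2),
        y_test=np.loadtxt(indir / "y_test.csv", delimiter=","),
        coef=coef,
        sigma=float(sidecar["sigma"]),
        config=config,
    )
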