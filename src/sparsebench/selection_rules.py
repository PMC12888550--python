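"""Rules converting method output into a binary selection vector.

Three conventions are used, matching how each family of methods reports
relevance:

* ``select_nonzero`` -- exact-zero patterns of penalized / refit solvers;
* ``select_pip`` -- thresholding posterior inclusion probabilities
  (mixture priors, SuSiE), default cutoff 0.5, boundary inclusive;
* ``kmeans_binarize`` -- continuous-shrinkage posteriors never produce
  exact zeros, so absolute posterior means are clustered by 1-D k-means
  with k in {2, 3, 4}; the largest cluster is labelled inactive and
  everything outside it is selected.  k is picked by the elbow rule on the
  within-cluster sum of squares: the k maximizing the relative WCSS drop
  from k-1 (k=1 WCSS as baseline), ties to the smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .base import MethodResult

__all__ = [
    "SelectionResult",
    "select_nonzero",
    "select_pip",
    "kmeans_binarize",
    "select",
    "RULE_FOR_METHOD",
]

#: method label -> selection rule name
RULE_FOR_METHOD = {
    "LASSO": "nonzero",
    "EL": "nonzero",
    "ALASSO": "nonzero",
    "SL": "nonzero",
    "SISL": "nonzero",
    "RFSFS": "nonzero",
    "RF": "nonzero",
    "SN": "pip_threshold",
    "SUSIE": "pip_threshold",
    "BL": "kmeans",
    "HS": "kmeans",
    "HSP": "kmeans",
    "RHS": "kmeans",
}


@dataclass
class SelectionResult:
    selected: np.ndarray  # length-p 0/1 vector
    rule: str
    rule_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=int)
        if not np.all((self.selected == 0) | (self.selected == 1)):
            raise ValueError("selected entries must be 0/1")

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


def select_nonzero(beta_hat: np.ndarray) -> SelectionResult:
    return SelectionResult(
        selected=(np.asarray(beta_hat) != 0.0).astype(int), rule="nonzero"
    )


def select_pip(pip: np.ndarray, threshold: float = 0.5) -> SelectionResult:
    pip = np.asarray(pip, dtype=float)
    if np.any((pip < 0) | (pip > 1)):
        raise ValueError("pip entries must lie in [0, 1]")
    return SelectionResult(
        selected=(pip >= threshold).astype(int),
        rule="pip_threshold",
        rule_params={"threshold": threshold},
    )


def _lloyd_1d(values: np.ndarray, centers: np.ndarray, n_iter: int = 100):
    """1-D Lloyd iterations; returns (labels, centers, wcss)."""
    centers = np.sort(np.asarray(centers, dtype=float))
    for _ in range(n_iter):
        labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        new_centers = centers.copy()
        for k in range(len(centers)):
            members = values[labels == k]
            if members.size:
                new_centers[k] = members.mean()
        new_centers = np.sort(new_centers)
        if np.allclose(new_centers, centers):
            centers = new_centers
            break
        centers = new_centers
    labels = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    wcss = float(np.sum((values - centers[labels]) ** 2))
    return labels, centers, wcss


def _kmeans_1d(values: np.ndarray, k: int, rng: np.random.Generator, n_restarts: int = 20):
    """Best-of-restarts 1-D k-means: one quantile-spread init plus random
    restarts drawn from the data."""
    best = None
    quantile_init = np.quantile(values, (np.arange(k) + 0.5) / k)
    inits = [quantile_init]
    for _ in range(n_restarts - 1):
        inits.append(rng.choice(values, size=k, replace=False)
                     if len(np.unique(values)) >= k else quantile_init)
    for init in inits:
        labels, centers, wcss = _lloyd_1d(values, init)
        if best is None or wcss < best[2] - 1e-12:
            best = (labels, centers, wcss)
    return best


def kmeans_binarize(
    values: np.ndarray,
    rng: np.random.Generator | None = None,
    ks: tuple[int, ...] = (2, 3, 4),
) -> SelectionResult:
    """Cluster non-negative relevance values (|posterior means|) and select
    everything outside the largest cluster."""
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("values must be non-negative (pass absolute posterior means)")
    rng = rng if rng is not None else np.random.default_rng(0)
    p = values.size
    wcss1 = float(np.sum((values - values.mean()) ** 2))
    if wcss1 == 0.0 or np.unique(values).size < 2:
        # all values identical: single degenerate cluster, nothing selected
        return SelectionResult(
            selected=np.zeros(p, dtype=int), rule="kmeans", rule_params={"k": 1}
        )
    fits = {}
    wcss = {1: wcss1}
    for k in ks:
        if np.unique(values).size < k:
            continue
        labels, centers, w = _kmeans_1d(values, k, rng)
        fits[k] = (labels, centers)
        wcss[k] = w
    # elbow: largest relative WCSS drop from k-1 (ties -> smaller k)
    best_k, best_drop = None, -np.inf
    for k in sorted(fits):
        prev = wcss.get(k - 1)
        if prev is None or prev <= 0:
            drop = 0.0
        else:
            drop = (prev - wcss[k]) / prev
        if drop > best_drop + 1e-12:
            best_k, best_drop = k, drop
    labels, centers = fits[best_k]
    counts = np.bincount(labels, minlength=best_k)
    largest = np.max(counts)
    candidates = np.flatnonzero(counts == largest)
    inactive = candidates[np.argmin(centers[candidates])]  # ties: smallest center
    selected = (labels != inactive).astype(int)
    return SelectionResult(
        selected=selected,
        rule="kmeans",
        rule_params={"k": int(best_k), "centers": centers.tolist()},
    )


def select(result: MethodResult, rng: np.random.Generator | None = None,
           pip_threshold: float = 0.5) -> SelectionResult:
    """Apply the selection rule registered for the method that produced
    ``result``."""
    rule = RULE_FOR_METHOD.get(result.method_name)
    if rule is None:
        rule = {"beta_hat": "nonzero", "pip": "pip_threshold",
                "posterior_mean": "kmeans"}[result.selection_carrier]
    if rule == "nonzero":
        return select_nonzero(result.beta_hat)
    if rule == "pip_threshold":
        return select_pip(result.pip, pip_threshold)
    return kmeans_binarize(np.abs(result.posterior_mean), rng)
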