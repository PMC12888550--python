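"""Two-stage screening selectors.

* ``sis_screen`` -- sure independence screening: rank features by absolute
  marginal Pearson correlation with the response and keep the top
  ``dn = floor(n / log n)``.
* ``rf_min_depth`` -- random-forest minimum-depth screening: grow a
  500-tree regression forest (bootstrap rows, p/3 features per split,
  terminal node size 5) and rank features by the average depth of their
  first (shallowest) split across trees; trees where a feature never splits
  contribute that tree's maximal depth + 1.  Keep the dn smallest.
* ``forward_bic`` -- greedy stepwise regression under BIC with a drop check
  each round.
* Composites: ``sisl`` (SIS then cross-validated LASSO), ``rfsfs``
  (minimum-depth screen then forward/BIC, OLS refit -- the two-step
  procedure this package benchmarks), and ``rf_select`` (the standalone
  depth-threshold forest selector).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .base import MethodResult
from .methods_penalized import PenaltyConfig, fit_lasso

__all__ = [
    "ScreeningResult",
    "ForwardPath",
    "screening_size",
    "sis_screen",
    "rf_min_depth",
    "forward_bic",
    "rfsfs",
    "sisl",
    "rf_select",
]


@dataclass
class ScreeningResult:
    kept: np.ndarray  # indices of retained features (best first)
    score: np.ndarray  # length-p ranking score
    dn: int
    higher_is_better: bool  # True for |correlation|, False for depth


@dataclass
class ForwardPath:
    steps: list = field(default_factory=list)  # (action, feature, bic)
    final: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    bic_trace: list = field(default_factory=list)


def screening_size(n: int) -> int:
    """dn = floor(n / log n) (natural log)."""
    if n < 3:
        raise ValueError("need n >= 3")
    return int(np.floor(n / np.log(n)))


def sis_screen(X: np.ndarray, y: np.ndarray) -> ScreeningResult:
    """Marginal-correlation screen keeping the top dn features."""
    n, p = X.shape
    dn = screening_size(n)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt(np.einsum("ij,ij->j", xc, xc) * (yc @ yc))
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.abs(xc.T @ yc) / denom
    score = np.nan_to_num(score, nan=0.0)  # constant columns score 0
    keep = min(dn, p)
    kept = np.argsort(-score, kind="stable")[:keep]
    return ScreeningResult(kept=kept, score=score, dn=dn, higher_is_better=True)


def _tree_min_depths(tree, p: int) -> np.ndarray:
    """Depth of each feature's shallowest split in one tree; features that
    never split get (max node depth + 1)."""
    n_nodes = tree.node_count
    depth = np.zeros(n_nodes, dtype=np.int64)
    left, right = tree.children_left, tree.children_right
    for node in range(n_nodes):  # parents precede children in sklearn arrays
        for child in (left[node], right[node]):
            if child != -1:
                depth[child] = depth[node] + 1
    max_depth = int(depth.max())
    out = np.full(p, max_depth + 1, dtype=float)
    internal = left != -1
    feats = tree.feature[internal]
    np.minimum.at(out, feats, depth[internal].astype(float))
    return out


def rf_min_depth(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    rng: np.random.Generator | None = None,
    mtry: float = 1 / 3,
    node_size: int = 5,
) -> ScreeningResult:
    """Minimum-depth screen from a Breiman regression forest."""
    n, p = X.shape
    if n < 10:
        raise ValueError("need n >= 10 for forest screening")
    if np.ptp(y) == 0:
        raise ValueError("response is constant; forest screening undefined")
    seed = int(rng.integers(2**31 - 1)) if rng is not None else 0
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=node_size,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    total = np.zeros(p)
    for est in forest.estimators_:
        total += _tree_min_depths(est.tree_, p)
    score = total / n_trees
    dn = screening_size(n)
    keep = min(dn, p)
    kept = np.argsort(score, kind="stable")[:keep]
    return ScreeningResult(kept=kept, score=score, dn=dn, higher_is_better=False)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    if X.shape[1] == 0:
        return float(y @ y)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r)


def _bic(rss: float, n: int, k: int) -> float:
    # k model terms + intercept
    return n * np.log(max(rss, 1e-300) / n) + (k + 1) * np.log(n)


def forward_bic(
    X: np.ndarray, y: np.ndarray, stepwise: bool = True, tol: float = 1e-10
) -> ForwardPath:
    """Greedy BIC-guided selection over the columns of X.

    Each round evaluates adding every unused column and (if ``stepwise``)
    dropping every included one; the single best action is accepted iff it
    strictly lowers the current BIC.  Stops when no action improves, or if
    the fit becomes exact (RSS = 0).
    """
    n, p = X.shape
    included: list[int] = []
    path = ForwardPath()
    current_rss = float(y @ y)
    current_bic = _bic(current_rss, n, 0)
    path.bic_trace.append(current_bic)
    while True:
        if current_rss <= max(tol * float(y @ y), 1e-12):
            break
        best = None  # (bic, action, feature)
        for j in range(p):
            if j in included:
                continue
            rss = _rss(X[:, included + [j]], y)
            bic = _bic(rss, n, len(included) + 1)
            if best is None or bic < best[0]:
                best = (bic, "add", j)
        if stepwise:
            for j in included:
                rest = [i for i in included if i != j]
                rss = _rss(X[:, rest], y)
                bic = _bic(rss, n, len(rest))
                if best is None or bic < best[0]:
                    best = (bic, "drop", j)
        if best is None or best[0] >= current_bic - tol:
            break
        bic, action, j = best
        if action == "add":
            included.append(j)
        else:
            included.remove(j)
        current_bic = bic
        current_rss = _rss(X[:, included], y)
        path.steps.append((action, j, bic))
        path.bic_trace.append(bic)
    path.final = np.array(sorted(included), dtype=int)
    return path


def _ols_refit(X: np.ndarray, y: np.ndarray, selected: np.ndarray) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    if selected.size:
        coef, *_ = np.linalg.lstsq(X[:, selected], y, rcond=None)
        beta[selected] = coef
    return beta


def rfsfs(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    rng: np.random.Generator | None = None,
    stepwise: bool = True,
) -> MethodResult:
    """Random-forest minimum-depth screening followed by forward selection
    under BIC; coefficients are the OLS refit on the final set."""
    t0 = time.perf_counter()
    screen = rf_min_depth(X, y, n_trees=n_trees, rng=rng)
    path = forward_bic(X[:, screen.kept], y, stepwise=stepwise)
    selected = screen.kept[path.final]
    beta = _ols_refit(X, y, selected)
    return MethodResult(
        method_name="RFSFS",
        beta_hat=beta,
        hyperparams={
            "dn": screen.dn,
            "screen_kept": screen.kept.copy(),
            "n_selected": int(selected.size),
        },
        runtime_s=time.perf_counter() - t0,
    )


def sisl(
    X: np.ndarray,
    y: np.ndarray,
    cfg: PenaltyConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MethodResult:
    """SIS screening followed by cross-validated LASSO on the kept columns."""
    t0 = time.perf_counter()
    screen = sis_screen(X, y)
    sub = fit_lasso(X[:, screen.kept], y, cfg, rng)
    beta = np.zeros(X.shape[1])
    beta[screen.kept] = sub.beta_hat
    return MethodResult(
        method_name="SISL",
        beta_hat=beta,
        hyperparams={"dn": screen.dn, **sub.hyperparams},
        runtime_s=time.perf_counter() - t0,
    )


def rf_select(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    rng: np.random.Generator | None = None,
) -> MethodResult:
    """Standalone forest selector: keep the top-dn minimum-depth features
    whose average depth is also below the forest-wide mean of average
    depths; coefficients are the OLS refit."""
    t0 = time.perf_counter()
    screen = rf_min_depth(X, y, n_trees=n_trees, rng=rng)
    threshold = float(screen.score.mean())
    selected = screen.kept[screen.score[screen.kept] < threshold]
    beta = _ols_refit(X, y, np.sort(selected))
    return MethodResult(
        method_name="RF",
        beta_hat=beta,
        hyperparams={"dn": screen.dn, "depth_threshold": threshold,
                     "n_selected": int(selected.size)},
        runtime_s=time.perf_counter() - t0,
    )
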