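"""Replicated benchmarking: metrics, method registry, stability profiles and
cross-scenario rank aggregation.

Selection quality is scored against the generating support with
FDR = FP/(TP+FP), FNR = FN/(TP+FN) and the F-score
2 P R / (P + R), P = 1 - FDR, R = 1 - FNR.  Zero-selection replicates take
FDR = 0 (no false discoveries were made); replicates with zero recall and
zero precision take F = 0 and are flagged degenerate, mirroring the
"unranked" treatment of total failures.  Prediction quality is the mean
squared prediction error of X beta_hat on the training rows (MSPE_in) and a
held-out test block (MSPE_out).

Ranking: within each scenario x metric, methods are ranked on their
replicate average (ascending for FDR/FNR/MSPE/runtime, descending for
F-score) with midrank ties, then averaged across scenarios into the
average (m) and median (m~) rank.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import methods_bayes, methods_penalized, methods_screening, methods_spike_slab, methods_susie
from .base import MethodResult
from .methods_bayes import McmcConfig
from .selection_rules import SelectionResult, select
from .simdata import SimConfig, SimulatedDataset, generate, standardize

logger = logging.getLogger("sparsebench")

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "confusion",
    "fdr",
    "fnr",
    "fscore",
    "mspe",
    "evaluate",
    "run_benchmark",
    "BenchmarkRun",
    "stability",
    "rank_methods",
    "ALL_METHODS",
    "fit_method",
]

#: ranking direction per metric (True = smaller is better)
ASCENDING_METRICS = {"fdr": True, "fnr": True, "mspe_in": True, "mspe_out": True,
                     "runtime_s": True, "fscore": False}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricRecord:
    method: str
    scenario_id: str
    replicate: int
    fdr: float
    fnr: float
    fscore: float
    mspe_in: float
    mspe_out: float
    runtime_s: float
    n_selected: int
    degenerate: bool = False
    failed: bool = False


def confusion(selection: SelectionResult | np.ndarray, support: np.ndarray, p: int) -> ConfusionCounts:
    """Cross-tabulate a selection against the true support (0-based indices)."""
    sel = selection.selected if isinstance(selection, SelectionResult) else np.asarray(selection)
    sel = sel.astype(bool)
    if sel.size != p:
        raise ValueError(f"selection length {sel.size} != p = {p}")
    truth = np.zeros(p, dtype=bool)
    support = np.asarray(support, dtype=int)
    if support.size and (support.min() < 0 or support.max() >= p):
        raise ValueError("support indices out of range")
    truth[support] = True
    tp = int(np.sum(sel & truth))
    fp = int(np.sum(sel & ~truth))
    fn = int(np.sum(~sel & truth))
    tn = int(np.sum(~sel & ~truth))
    return ConfusionCounts(tp, fp, fn, tn)


def fdr(c: ConfusionCounts) -> float:
    """FP / (TP + FP); 0 when nothing was selected."""
    return c.fp / (c.tp + c.fp) if c.tp + c.fp > 0 else 0.0


def fnr(c: ConfusionCounts) -> float:
    """FN / (TP + FN); 0 when the support is empty."""
    return c.fn / (c.tp + c.fn) if c.tp + c.fn > 0 else 0.0


def fscore(c: ConfusionCounts) -> float:
    """Harmonic mean of precision (1 - FDR) and recall (1 - FNR); 0 when
    both vanish (degenerate selection)."""
    prec = 1.0 - fdr(c)
    rec = 1.0 - fnr(c)
    if prec + rec == 0.0:
        return 0.0
    return 2.0 * prec * rec / (prec + rec)


def is_degenerate(c: ConfusionCounts) -> bool:
    """Total miss: no true positive at all (FNR = 1, F = 0)."""
    return c.tp == 0 and c.fn > 0


def mspe(beta_hat: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Mean squared prediction error of y_hat = X beta_hat."""
    r = y - X @ beta_hat
    return float(r @ r) / len(y)


# ---------------------------------------------------------------------------
# method registry


def _mcmc(seed: int, n_iter: int, burn_in: int) -> McmcConfig:
    return McmcConfig(n_iter=n_iter, burn_in=burn_in, seed=seed)


def fit_method(
    name: str,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    oracle_k: int | None = None,
    n_iter: int = 5000,
    burn_in: int = 1000,
) -> MethodResult:
    """Fit one registered method on standardized data.

    ``oracle_k`` is the true active-set size; SN, RHS and SuSiE receive it
    as calibration (expected model size / number of effects), mirroring the
    benchmark protocol.  MCMC methods draw their chain seed from ``rng``.
    """
    n, p = X.shape
    seed = int(rng.integers(2**31 - 1))
    if name == "LASSO":
        return methods_penalized.fit_lasso(X, y, rng=rng)
    if name == "EL":
        return methods_penalized.fit_elastic_net(X, y, rng=rng)
    if name == "ALASSO":
        return methods_penalized.fit_alasso(X, y, rng=rng)
    if name == "BL":
        return methods_bayes.fit_blasso(X, y, _mcmc(seed, n_iter, burn_in))
    if name == "HS":
        return methods_bayes.fit_horseshoe(X, y, _mcmc(seed, n_iter, burn_in))
    if name == "HSP":
        return methods_bayes.fit_horseshoe_plus(X, y, _mcmc(seed, n_iter, burn_in))
    if name == "RHS":
        p0 = oracle_k if oracle_k else max(1, min(n - 1, p // 10))
        return methods_bayes.fit_reg_horseshoe(X, y, _mcmc(seed, n_iter, burn_in), p0=p0)
    if name == "SN":
        omega = oracle_k / p if oracle_k else 0.5
        omega = float(np.clip(omega, 1e-4, 1 - 1e-4))
        cfg = methods_spike_slab.SpikeSlabConfig(omega=omega)
        return methods_spike_slab.fit_ssvs(X, y, cfg, _mcmc(seed, n_iter, burn_in))
    if name == "SL":
        return methods_spike_slab.fit_sslasso(X, y)
    if name == "SUSIE":
        L = oracle_k if oracle_k else min(10, p)
        return methods_susie.fit_susie(X, y, L=L)
    if name == "SISL":
        return methods_screening.sisl(X, y, rng=rng)
    if name == "RF":
        return methods_screening.rf_select(X, y, rng=rng)
    if name == "RFSFS":
        return methods_screening.rfsfs(X, y, rng=rng)
    raise ValueError(f"unknown method {name!r}")


ALL_METHODS = ["LASSO", "EL", "ALASSO", "BL", "HS", "HSP", "RHS", "SN", "SL",
               "SUSIE", "RF", "SISL", "RFSFS"]


# ---------------------------------------------------------------------------
# benchmark driver


@dataclass
class BenchmarkRun:
    records: pd.DataFrame
    selections: dict  # (scenario_id, method, replicate) -> selected index array


def replicate_seed(base_seed: int, scenario_idx: int, replicate: int) -> int:
    """Deterministic per-replicate dataset seed, identical across methods."""
    ss = np.random.SeedSequence([base_seed, scenario_idx, replicate])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def evaluate(
    result: MethodResult,
    selection: SelectionResult,
    dataset: SimulatedDataset,
    std,
    scenario_id: str,
    replicate: int,
) -> MetricRecord:
    """Score one (method, dataset) pair.

    Prediction uses the OLS refit on the selected set for methods whose
    selection is a set (screening/refit methods already return refit
    coefficients); otherwise the method's own point estimate.
    """
    c = confusion(selection, dataset.support, dataset.config.p)
    beta = result.beta_hat
    return MetricRecord(
        method=result.method_name,
        scenario_id=scenario_id,
        replicate=replicate,
        fdr=fdr(c),
        fnr=fnr(c),
        fscore=fscore(c),
        mspe_in=mspe(beta, std.X_train, std.y_train),
        mspe_out=mspe(beta, std.X_test, std.y_test),
        runtime_s=result.runtime_s,
        n_selected=int(selection.selected.sum()),
        degenerate=is_degenerate(c),
    )


def run_benchmark(
    scenarios: list[SimConfig] | dict[str, SimConfig],
    methods: list[str],
    reps: int,
    base_seed: int = 0,
    n_iter: int = 5000,
    burn_in: int = 1000,
) -> BenchmarkRun:
    """Paired-replicate benchmark: every method sees the identical dataset
    at each (scenario, replicate); a method failure yields a record with
    missing metrics and the run continues."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not isinstance(scenarios, dict):
        scenarios = {f"scenario_{i}": cfg for i, cfg in enumerate(scenarios)}
    rows = []
    selections = {}
    for si, (sid, cfg) in enumerate(scenarios.items()):
        for rep in range(reps):
            seed = replicate_seed(base_seed, si, rep)
            dataset = generate(dataclasses.replace(cfg, seed=seed))
            std = standardize(dataset)
            oracle_k = dataset.support.size
            for method in methods:
                method_rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [base_seed, si, rep, zlib.crc32(method.encode()) % 2**31]
                    )
                )
                try:
                    t0 = time.perf_counter()
                    result = fit_method(
                        method, std.X_train, std.y_train, method_rng,
                        oracle_k=oracle_k, n_iter=n_iter, burn_in=burn_in,
                    )
                    result.runtime_s = time.perf_counter() - t0
                    sel = select(result, method_rng)
                except Exception:
                    logger.exception("%s failed on %s replicate %d", method, sid, rep)
                    rows.append(
                        MetricRecord(
                            method=method, scenario_id=sid, replicate=rep,
                            fdr=np.nan, fnr=np.nan, fscore=np.nan,
                            mspe_in=np.nan, mspe_out=np.nan, runtime_s=np.nan,
                            n_selected=0, failed=True,
                        )
                    )
                    continue
                rows.append(evaluate(result, sel, dataset, std, sid, rep))
                selections[(sid, method, rep)] = sel.indices
    return BenchmarkRun(records=pd.DataFrame([r.__dict__ for r in rows]),
                        selections=selections)


# ---------------------------------------------------------------------------
# stability and ranking


def stability(run: BenchmarkRun, scenario_id: str, method: str,
              important: np.ndarray, p: int) -> pd.DataFrame:
    """Per-feature selection probabilities across replicates, with group
    medians for important / non-important features."""
    keys = [k for k in run.selections if k[0] == scenario_id and k[1] == method]
    if len(keys) < 2:
        raise ValueError("need at least 2 replicates with stored selections")
    counts = np.zeros(p)
    for k in keys:
        counts[run.selections[k]] += 1
    prob = counts / len(keys)
    mask = np.zeros(p, dtype=bool)
    mask[np.asarray(important, dtype=int)] = True
    return pd.DataFrame(
        {
            "feature": np.arange(1, p + 1),  # 1-based in reports
            "selection_probability": prob,
            "important": mask,
        }
    )


def stability_medians(table: pd.DataFrame) -> dict[str, float]:
    imp = table.loc[table["important"], "selection_probability"]
    non = table.loc[~table["important"], "selection_probability"]
    return {"important_median": float(imp.median()),
            "nonimportant_median": float(non.median())}


def rank_methods(records: pd.DataFrame, metrics: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Average (m) and median (m~) cross-scenario rank per method x metric.

    Within each scenario, a method is excluded ("unranked") for the
    selection metrics if every replicate was degenerate, and excluded
    entirely if every replicate failed.
    """
    metrics = metrics or ("fdr", "fnr", "fscore", "mspe_in", "mspe_out", "runtime_s")
    rows = []
    for sid, group in records.groupby("scenario_id"):
        ok = group[~group["failed"]]
        means = ok.groupby("method").agg(
            {m: "mean" for m in metrics} | {"degenerate": "all"}
        )
        for metric in metrics:
            sub = means
            if metric in ("fdr", "fnr", "fscore"):
                sub = means[~means["degenerate"]]
            vals = sub[metric].dropna()
            if vals.empty:
                continue
            ranks = rankdata(vals.values if ASCENDING_METRICS[metric] else -vals.values,
                             method="average")
            for method, rank in zip(vals.index, ranks):
                rows.append({"scenario_id": sid, "method": method,
                             "metric": metric, "rank": rank})
    long = pd.DataFrame(rows)
    if long.empty:
        return pd.DataFrame(columns=["method", "metric", "m", "m_med"])
    out = (
        long.groupby(["method", "metric"])["rank"]
        .agg(m="mean", m_med="median")
        .reset_index()
    )
    return out
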