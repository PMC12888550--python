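"""Shared result containers used by every selection method."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: which vector a method's selection rule consumes
SELECTION_CARRIERS = ("beta_hat", "pip", "posterior_mean")


@dataclass
class MethodResult:
    """Output of one method on one dataset.

    ``beta_hat`` always holds the point estimate used for prediction.
    ``selection_carrier`` names the vector the method's declared selection
    rule consumes: exact-zero patterns for penalized solvers, posterior
    inclusion probabilities for mixture priors and SuSiE, and absolute
    posterior means (clustered) for the continuous-shrinkage samplers.
    """

    method_name: str
    beta_hat: np.ndarray
    pip: np.ndarray | None = None
    posterior_mean: np.ndarray | None = None
    hyperparams: dict = field(default_factory=dict)
    runtime_s: float = 0.0
    selection_carrier: str = "beta_hat"
    converged: bool = True

    def __post_init__(self) -> None:
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        if self.selection_carrier not in SELECTION_CARRIERS:
            raise ValueError(f"unknown selection carrier {self.selection_carrier!r}")
        if self.pip is not None:
            self.pip = np.asarray(self.pip, dtype=float)
            if np.any((self.pip < 0) | (self.pip > 1)):
                raise ValueError("pip entries must lie in [0, 1]")

    def to_json(self, path: str | Path | None = None) -> str:
        """Sparse-encoded JSON (coefficients as 1-based index:value pairs)."""
        nz = np.flatnonzero(self.beta_hat)
        hyper = {
            k: _jsonable(v)
            for k, v in self.hyperparams.items()
            if _jsonable(v) is not _SKIP
        }
        payload = {
            "method_name": self.method_name,
            "p": int(self.beta_hat.size),
            "beta_hat": {str(j + 1): float(self.beta_hat[j]) for j in nz},
            "hyperparams": hyper,
            "runtime_s": self.runtime_s,
            "selection_carrier": self.selection_carrier,
            "converged": self.converged,
        }
        if self.pip is not None:
            payload["pip"] = [float(v) for v in self.pip]
        if self.posterior_mean is not None:
            payload["posterior_mean"] = [float(v) for v in self.posterior_mean]
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


_SKIP = object()


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (bool, int, float, str, type(None), list, tuple, dict)):
        return v
    return _SKIP  # rich objects (fitted models, traces) stay in memory only
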