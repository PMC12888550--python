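import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_regression(n, p, support, beta_vals, sigma, seed=0, standardized=True):
    """Small linear-model dataset with standardized columns / centered y."""
    r = np.random.default_rng(seed)
    X = r.standard_normal((n, p))
    if standardized:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    beta = np.zeros(p)
    beta[np.asarray(support, dtype=int)] = beta_vals
    y = X @ beta + sigma * r.standard_normal(n)
    if standardized:
        y = y - y.mean()
    return X, y, beta


@pytest.fixture
def toy_regression():
    return make_regression
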