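import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_glm_instance(rng, family, n=None, q=None, intercept=True):
    """Draw a random design/response pair for the given family."""
    n = n or int(rng.integers(10, 31))
    q = q or int(rng.integers(2, 5))
    X = rng.normal(size=(n, q))
    if intercept:
        X[:, 0] = 1.0
    beta = rng.normal(scale=0.4, size=q)
    eta = X @ beta
    if family == "gaussian":
        y = eta + rng.normal(size=n)
    elif family == "binomial":
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    else:
        y = rng.poisson(np.exp(np.clip(eta, -10, 3))).astype(float)
    return X, y


def separable_design(rng, n=None):
    """A binomial design/response with complete separation on the slope."""
    n = n or int(rng.integers(4, 13))
    x = np.sort(rng.normal(size=n))
    cut = rng.integers(1, n)  # at least one 0 and one 1
    y = (np.arange(n) >= cut).astype(float)
    X = np.column_stack([np.ones(n), x])
    return X, y
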