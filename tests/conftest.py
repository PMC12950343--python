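import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_strata():
    """200 days, ~20 strata, 3 covariates, mild stratum baselines."""
    rng = np.random.default_rng(7)
    n, n_strata, p = 200, 20, 3
    codes = np.repeat(np.arange(n_strata), n // n_strata)
    X = rng.normal(size=(n, p))
    beta = np.array([0.3, -0.2, 0.1])
    eta = 0.4 + X @ beta + 0.3 * rng.normal(size=n_strata)[codes]
    y = rng.poisson(np.exp(eta))
    return X, y, codes, beta
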