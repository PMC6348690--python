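import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ar1_unit_variance(rho, n, rng):
    """Stationary AR(1) with unit marginal variance (test helper)."""
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    sd = np.sqrt(1 - rho * rho)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + sd * e[t]
    return x
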