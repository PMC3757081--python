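import numpy as np
import pytest

from taswitch import REFERENCE, BindingConstants, TotalPool


@pytest.fixture
def reference():
    return REFERENCE


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_pools(rng, n, lo=1e-3, hi=1e3):
    """Log-uniform random (pool, constants) instances."""
    for _ in range(n):
        a, t, k1, k2 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=4))
        yield TotalPool(float(a), float(t)), BindingConstants(float(k1), float(k2))
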