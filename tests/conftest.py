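import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_xy(rng):
    """A modest n > p regression instance with genuine signal."""
    n, p = 60, 20
    X = (rng.random((n, p)) < 0.5).astype(float)
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(scale=2.0, size=n)
    return X, y, beta


@pytest.fixture
def wide_xy(rng):
    """A p > n instance, the regime where the dual form matters."""
    n, p = 40, 120
    X = (rng.random((n, p)) < 0.5).astype(float)
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(scale=3.0, size=n)
    return X, y, beta
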