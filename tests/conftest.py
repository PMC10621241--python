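import numpy as np
import pytest

from ebmf import ObservedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def rank1_noiseless():
    """A small exact rank-1 matrix with its generating vectors."""
    rng = np.random.default_rng(3)
    u = rng.standard_normal(30)
    v = rng.standard_normal(20)
    return ObservedMatrix(np.outer(u, v), None), u, v


def masked_rank1(seed: int, n: int = 40, p: int = 30, frac_missing: float = 0.3):
    """Seeded rank-1 + noise draw with a random missingness pattern."""
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    v = rng.standard_normal(p)
    Y = np.outer(u, v) + 0.1 * rng.standard_normal((n, p))
    mask = rng.random((n, p)) >= frac_missing
    return ObservedMatrix(np.where(mask, Y, 0.0), mask), np.outer(u, v)
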