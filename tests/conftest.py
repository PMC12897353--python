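import numpy as np
import pytest

from scirt.expression_io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """8 cells x 6 genes of random non-negative reals."""
    return ExpressionMatrix(rng.uniform(0, 10, size=(8, 6)))


@pytest.fixture
def two_cluster_matrix(rng):
    """Two well-separated cell groups (rows 0-9 vs 10-19)."""
    a = rng.uniform(0, 1, size=(10, 12))
    b = rng.uniform(0, 1, size=(10, 12)) + 20.0
    values = np.vstack([a, b])
    labels = np.array([0] * 10 + [1] * 10)
    return ExpressionMatrix(values), labels
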