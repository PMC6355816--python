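import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def toy_data(rng):
    """Small unstructured phenotype/genotype pair for exactness checks."""
    n, K = 24, 3
    Y = rng.standard_normal((n, K))
    x = rng.binomial(2, 0.3, n).astype(float)
    x[0] = 1.0  # guarantee polymorphism
    return Y, x
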