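import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_gene(rng):
    """Beta-value block (20 samples x 5 CpGs) with balanced labels."""
    x = rng.beta(46.36, 52.28, size=(20, 5))
    y = np.array([0] * 10 + [1] * 10)
    return x, y
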