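import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tall_problem(rng):
    """Well-conditioned tall regression problem (d=50, p=10, t=4)."""
    X = rng.standard_normal((50, 10))
    Y = rng.standard_normal((50, 4))
    return X, Y
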