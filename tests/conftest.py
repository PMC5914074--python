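import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_pd(rng):
    """Factory for random symmetric positive definite matrices."""

    def make(m: int) -> np.ndarray:
        A = rng.normal(size=(m, m))
        return A @ A.T + m * np.eye(m)

    return make
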