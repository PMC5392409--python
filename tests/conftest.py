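import numpy as np
import pytest

from l12glpca import SimulationSpec


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_spec():
    """Scaled-down planted-factor generator for fast tests."""
    return SimulationSpec(m=200, n=10, block_size=10, seed=0)


def random_orthonormal(rng, n, k):
    Q, _ = np.linalg.qr(rng.standard_normal((n, k)))
    return Q
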