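import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_suite():
    """The nine standard scenes at a small size (shared, read-only)."""
    from dlpr import make_test_suite

    return make_test_suite((32, 32), seed=0)


def random_unit_atoms(rng, w2, k):
    a = rng.standard_normal((w2, k)) + 1j * rng.standard_normal((w2, k))
    return a / np.linalg.norm(a, axis=0)
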