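import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def diagonal():
    """The minimal strictly increasing toy: every point is a ceiling point."""
    from ncaskew import XYDataset

    return XYDataset([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


@pytest.fixture
def five_point():
    """Five points with an x-tie and one dominated point; peers are
    (1,2), (2,5), (4,6)."""
    from ncaskew import XYDataset

    return XYDataset([1.0, 2.0, 2.0, 3.0, 4.0], [2.0, 1.0, 5.0, 4.0, 6.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20170913)


def random_dataset(rng, n=None):
    """A generic continuous dataset with non-degenerate scope."""
    n = n or int(rng.integers(5, 200))
    return rng.normal(size=n), rng.normal(size=n)
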