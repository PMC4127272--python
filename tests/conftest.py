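import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240717)


@pytest.fixture
def phantom128():
    from sbpn import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(dims=(128, 128), seed=3))


def random_gray(rng, m, n):
    """A random 8-bit test matrix."""
    return rng.integers(0, 256, size=(m, n), dtype=np.uint8)
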