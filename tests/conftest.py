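import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def hexapeptide():
    """Small bundled synthetic hexapeptide system (n = 10 angles)."""
    from torsiondyn import fixture_hexapeptide

    return fixture_hexapeptide(n_frames=1200)


@pytest.fixture
def random_wrapped(rng):
    """Random wrapped angle matrix, 300 frames x 7 angles."""
    return rng.uniform(-180.0, 180.0, size=(300, 7))
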