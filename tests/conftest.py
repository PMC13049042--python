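import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from mirrormetry.phantom import FemurPhantomSpec, make_femur_phantom  # noqa: E402


@pytest.fixture(scope="session")
def phantom_spec():
    return FemurPhantomSpec()


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    """(left, right, landmarks) of the default bilateral phantom."""
    return make_femur_phantom(phantom_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
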