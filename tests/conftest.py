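import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")

from tickdae.experiments import get_preset


@pytest.fixture(scope="session")
def bi():
    """Cooperative-feeding / density-dependent-grooming parameter set."""
    return get_preset("bi")


@pytest.fixture(scope="session")
def quadri():
    """Holling-III attachment / biting-reactive-grooming parameter set."""
    return get_preset("quadri")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
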