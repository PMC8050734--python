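import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def t_grid():
    """Default design: ZT 2..22 every 4 h, 4 replicates."""
    return np.tile([2.0, 6.0, 10.0, 14.0, 18.0, 22.0], 4)


def cosine(t, mesor, amplitude, acrophase, tau=24.0):
    return mesor + amplitude * np.cos(2 * np.pi * (np.asarray(t) - acrophase) / tau)


@pytest.fixture
def cosine_fn():
    return cosine
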