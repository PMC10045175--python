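import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prepost import BEAT_THE_BLUES, CorrelationSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def btb() -> CorrelationSpec:
    """Printed parameter estimates from the Beat the Blues depression trial."""
    return BEAT_THE_BLUES


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230328)
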