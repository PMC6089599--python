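import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ldbuffer import KineticParams

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def params() -> KineticParams:
    """Reference calibration: K_HL = 2, k_eff = 0.005 /s, separation ratio 18."""
    return KineticParams()


@pytest.fixture
def times_20min() -> np.ndarray:
    return np.arange(0.0, 1201.0, 60.0)
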