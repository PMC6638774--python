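import numpy as np
import pytest

from polcompass.compass_core import CompassModel, GatingParams
from polcompass.dra_sensor import build_dra


@pytest.fixture(scope="session")
def array():
    return build_dra()


@pytest.fixture(scope="session")
def compass(array):
    """Default (tilt-calibrated) compass; session-scoped so the attitude
    calibrations are computed once."""
    return CompassModel(array)


@pytest.fixture(scope="session")
def gate_compass(array):
    """Printed architecture: gated sum-of-sinusoids decode."""
    return CompassModel(array, tilt_mode="gate")


@pytest.fixture(scope="session")
def ungated_compass(array):
    """Printed architecture with the gate disabled (all weights equal)."""
    return CompassModel(array, gating=GatingParams(enabled=False), tilt_mode="off")


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
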