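import numpy as np
import pytest

from fatiguekit.calibration import (
    FatigueState,
    default_ecg_calibration,
    default_emg_calibration,
)


@pytest.fixture(scope="session")
def emg_cal_a():
    return default_emg_calibration(FatigueState.A)


@pytest.fixture(scope="session")
def ecg_cal_a():
    return default_ecg_calibration(FatigueState.A)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
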