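import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rptdose import (
    BiodistSimParams,
    BiodistributionStudy,
    LUTETIUM_177,
    TissueTimeCourse,
    simulate_biodistribution,
)

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_study() -> BiodistributionStudy:
    """Default synthetic study with no inter-animal noise (exact TAC values)."""
    return simulate_biodistribution(BiodistSimParams(noise_cv=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_study() -> BiodistributionStudy:
    return simulate_biodistribution(BiodistSimParams(seed=7))


@pytest.fixture
def mono_exp_timecourse() -> TissueTimeCourse:
    """Noiseless mono-exponential curve C(t) = 10 exp(-0.01 t)."""
    times = np.array([4.0, 24.0, 48.0, 96.0, 168.0, 240.0])
    vals = 10.0 * np.exp(-0.01 * times)
    return TissueTimeCourse.from_observations("organ", [(t, [v]) for t, v in zip(times, vals)])


@pytest.fixture
def nuclide():
    return LUTETIUM_177
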