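import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from egmscore import CohortParams, WaveformParams, simulate_cohort, simulate_waveform

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def waveform():
    """One default simulated recording with per-beat ground truth."""
    return simulate_waveform(WaveformParams(seed=11))


@pytest.fixture(scope="session")
def noiseless_waveform():
    return simulate_waveform(WaveformParams(seed=11, noise_sd_mv=0.0))


@pytest.fixture(scope="session")
def cohort():
    """A validation-study-sized simulated cohort (144 patients)."""
    return simulate_cohort(CohortParams(seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort for distributional checks (~5000 signals)."""
    return simulate_cohort(CohortParams(n_patients=2100, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
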