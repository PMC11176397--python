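import numpy as np
import pytest

from sahq.synthetic_cohort import CohortConfig, EEGProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_profile():
    """Desk-scale EEG profile: 200 Hz, 10 min, no pink noise/artifacts so
    analytic band-power expectations apply exactly."""
    return EEGProfile(fs_hz=200.0, duration_s=600.0, pink_gain=0.0,
                      artifact_rate=0.0)


@pytest.fixture
def tiny_cohort(fast_profile):
    return CohortConfig(n_per_group=2, days=(2, 7), seed=11, eeg=fast_profile)
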