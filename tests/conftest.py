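import numpy as np
import pytest

from phsent import CohortConfig, generate_recording_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_recordings():
    """Small noiseless waveform cohort shared by segmentation/feature tests."""
    config = CohortConfig(
        n_patient=2, n_control=2, n_cycles=30, seed=7,
        regularity_shift=0.5, murmur_level=0.0,
    )
    return generate_recording_cohort(config)
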