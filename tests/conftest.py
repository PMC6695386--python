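import numpy as np
import pytest

from radvital import CarotidVitalModel, PhysioProfile, SimConfig, simulate_recording


@pytest.fixture(scope="session")
def nsr_recording():
    """Default 60-s NSR recording (seed 1) with ground truth."""
    return simulate_recording(SimConfig(seed=1), PhysioProfile())


@pytest.fixture(scope="session")
def nsr_results(nsr_recording):
    frames, _ = nsr_recording
    return CarotidVitalModel(frames).fit()


@pytest.fixture(scope="session")
def peaf_recording():
    """Default 60-s PeAF recording (seed 1) with ground truth."""
    return simulate_recording(SimConfig(seed=1), PhysioProfile(rhythm="PeAF"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
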