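import numpy as np
import pytest

from magstep import DetectorConfig, GaitSimConfig, SensorSpec, design_lowpass


@pytest.fixture(scope="session")
def default_filter():
    return design_lowpass()


@pytest.fixture(scope="session")
def detector_config():
    return DetectorConfig()


@pytest.fixture
def noiseless_walk_config():
    """60 s walk at 5 km/h with sensor noise and quantisation disabled."""
    return GaitSimConfig(
        walk_speed_kmh=5.0,
        sensor=SensorSpec(noise_sigma_uT=0.0),
        quantize=False,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20211123)
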