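import numpy as np
import pytest

from diazosip.synthetic_data import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_config():
    return ScenarioConfig(seed=7)


@pytest.fixture
def noiseless_config():
    return ScenarioConfig(seed=7, sensor_noise_frac=0.0, measurement_cv=0.0)
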