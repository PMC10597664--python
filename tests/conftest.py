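import numpy as np
import pytest
from hypothesis import settings

import effluxion as ex

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def protocol():
    return ex.StimulationProtocol()


@pytest.fixture
def quiet_release_cfg():
    """Noise-free release simulator at the default study conditions."""
    return ex.ReleaseSimConfig(poisson_noise=False)


@pytest.fixture
def rng():
    return np.random.default_rng(20231010)
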