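import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def lipidome():
    from lipidflux.simulate import default_lipidome

    return default_lipidome()


@pytest.fixture
def noise_off():
    from lipidflux.simulate import NoiseModel

    return NoiseModel.off(p_13c=0.0107)


@pytest.fixture
def noise_off_p0():
    from lipidflux.simulate import NoiseModel

    return NoiseModel.off(p_13c=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
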