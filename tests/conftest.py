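import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "qfa",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("qfa")


@pytest.fixture
def rng():
    return np.random.default_rng(20090101)


@pytest.fixture
def small_series():
    """Noiseless logistic curve (G0=43, r=4, K=20000) at 13 times in [0, 4] d."""
    from qfa import LogisticParams, logistic_density

    t = np.linspace(0.0, 4.0, 13)
    params = LogisticParams(g0=43.0, r=4.0, K=20000.0)
    return t, logistic_density(t, params), params
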