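import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_walk():
    from restless import generate_walk

    return generate_walk(300, 3, 0.6667, 0.2, (0.1, 0.9), seed=123)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(987654321)
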