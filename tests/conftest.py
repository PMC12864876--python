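import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scene_config():
    from pestpyramid import SceneConfig
    return SceneConfig(seed=7)


@pytest.fixture(scope="session")
def small_split(scene_config):
    """40-scene split shared by unit smoke tests (not the acceptance runs)."""
    from pestpyramid import generate_dataset
    return generate_dataset(scene_config, 40, 0.75)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
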