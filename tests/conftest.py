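import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from glomkit.synthetic import SlideSpec, generate_slide

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_slide():
    """One default-resolution slide (2 µm/px) with its ground truth."""
    return generate_slide(SlideSpec(seed=42))


@pytest.fixture(scope="session")
def small_slide():
    """A small slide for quick structural checks."""
    return generate_slide(SlideSpec(width_px=800, height_px=800, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
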