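import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_image(rng):
    """A small non-degenerate grayscale test image on the 0-255 scale."""
    return rng.uniform(0.0, 255.0, size=(24, 36))


@pytest.fixture(scope="session")
def two_class_small():
    """Session-cached synthetic two-class set (40 images, 81x108 px)."""
    from scenedegrade import synthetic_data as syn

    params = syn.SyntheticImageParams(height_px=81, width_px=108)
    images, manifest = syn.gen_two_class_set(20, params, seed=7)
    return images, manifest, params
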