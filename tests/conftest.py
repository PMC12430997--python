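import numpy as np
import pytest

from paddyscan.imaging import RGBImage
from paddyscan.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A compact anomaly-free scene used by several suites."""
    return generate_scene(SceneConfig(image_size=(192, 192), n_plants=9,
                                      anomaly_fraction=0.0, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def uniform_image():
    def make(rgb, shape=(20, 20), scale="unit"):
        px = np.empty(shape + (3,))
        px[:] = rgb
        return RGBImage(px, scale=scale, id="uniform")
    return make
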