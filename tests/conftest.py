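import numpy as np
import pytest

from birdtrack.boxes import BBox
from birdtrack.simulate import ScenarioConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene():
    """A quick-to-simulate scene for pipeline tests: 12 birds, 3 species,
    20 s at 10 fps on a 320 x 320 image, noise-free."""
    return ScenarioConfig(
        height=320,
        width=320,
        fps=10.0,
        duration_s=20.0,
        n_species=3,
        n_birds=12,
        box_size_range=(15.0, 35.0),
        seed=7,
    )


def random_box(rng, lo=0.0, hi=100.0, min_size=1.0, max_size=40.0) -> BBox:
    x = rng.uniform(lo, hi - max_size)
    y = rng.uniform(lo, hi - max_size)
    w = rng.uniform(min_size, max_size)
    h = rng.uniform(min_size, max_size)
    return BBox(x, y, x + w, y + h)
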