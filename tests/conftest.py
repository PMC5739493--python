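import numpy as np
import pytest

from yolkvision.config import DEFAULT_RANGES
from yolkvision.fixtures import EggScene, make_dataset, make_egg_image
from yolkvision.preprocess import preprocess


def _scene(label, overlap=0.35, noise=0.0, seed=11, radius=36.0):
    center = (200.0, 150.0)
    if label == "SY":
        centers = [center]
    else:
        centers = EggScene.double_yolk_centers(center, radius, overlap, angle=0.1)
    return EggScene(
        image_width=400, image_height=300, egg_center=center,
        egg_semi_axes=(100.0, 73.0), yolk_centers=centers, yolk_radius=radius,
        yolk_overlap_fraction=overlap if label == "DY" else 1.0,
        background_level=DEFAULT_RANGES.background_level,
        albumen_level=DEFAULT_RANGES.albumen_level,
        yolk_level=DEFAULT_RANGES.yolk_level,
        noise_sigma=noise, label=label, seed=seed,
        falloff=DEFAULT_RANGES.falloff)


@pytest.fixture(scope="session")
def sy_scene():
    return _scene("SY")


@pytest.fixture(scope="session")
def dy_scene():
    return _scene("DY", overlap=0.3)


@pytest.fixture(scope="session")
def separated_scene():
    return _scene("DY", overlap=-0.15)


@pytest.fixture(scope="session")
def make_scene():
    return _scene


@pytest.fixture(scope="session")
def sy_roipair(sy_scene):
    return preprocess(make_egg_image(sy_scene))


@pytest.fixture(scope="session")
def dy_roipair(dy_scene):
    return preprocess(make_egg_image(dy_scene))


@pytest.fixture(scope="session")
def separated_roipair(separated_scene):
    return preprocess(make_egg_image(separated_scene))


@pytest.fixture(scope="session")
def small_dataset():
    """12 noisy images, 6 per class, for pipeline-level checks."""
    return make_dataset(6, 6, seed=1)


def random_contour(rng, n=48):
    """Smooth random star-shaped closed contour (no self-intersection)."""
    theta = 2 * np.pi * np.arange(n) / n
    r = 10.0 + np.zeros(n)
    for h in range(2, 6):
        r += rng.uniform(-1.5, 1.5) * np.cos(h * theta + rng.uniform(0, 2 * np.pi))
    from yolkvision.shape import Contour
    return Contour(np.column_stack([r * np.cos(theta), r * np.sin(theta)]))
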