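import numpy as np
import pytest

from dewquant import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def glass_scene():
    """One clean glass-background scene with mid-sized droplets."""
    cfg = SceneConfig(
        image_width=160,
        image_height=160,
        n_droplets=4,
        droplet_diameter_range=(18, 36),
        background_kind="glass",
        border_margin_px=14,
        seed=11,
    )
    return generate_scene(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_masks(rng, n, shape_max=12):
    """Random small binary masks of assorted shapes and densities."""
    masks = []
    for _ in range(n):
        h = rng.integers(3, shape_max + 1)
        w = rng.integers(3, shape_max + 1)
        density = rng.uniform(0.15, 0.8)
        masks.append((rng.random((h, w)) < density).astype(np.uint8))
    return masks
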