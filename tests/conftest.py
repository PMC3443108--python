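import numpy as np
import pytest

from plaquebeads import (
    BackgroundModel,
    BeadSpec,
    DetectionParams,
    NoiseModel,
    SceneConfig,
    generate_scene,
    plant_beads,
    tile_scene,
)


def quiet_config(width=60.0, height=60.0, depth=40.0, **kwargs):
    """Scene config with zero background and zero noise: only what is
    planted is in the volume."""
    return SceneConfig(
        width_um=width, height_um=height, depth_um=depth,
        background=BackgroundModel(fiber_amplitude=0, autofluor_mean=0,
                                   autofluor_variation=0, lipid_amplitude=0,
                                   lipid_blob_count=0),
        noise=NoiseModel(gaussian_sigma=0, poisson_gain=0),
        **kwargs,
    )


@pytest.fixture
def params():
    return DetectionParams()


@pytest.fixture
def bead_spec():
    return BeadSpec()


@pytest.fixture
def quiet_scene():
    """Noise-free empty 60x60x40 um scene."""
    return generate_scene(quiet_config(), seed=0)


@pytest.fixture
def planted_tileset(bead_spec):
    """Noise-free scene with 30 separated beads, tiled 2x2 with 10% overlap."""
    scene = generate_scene(quiet_config(), seed=1)
    plant_beads(scene, 30, bead_spec, clump_fraction=0.0, seed=7)
    return tile_scene(scene, 2, 2, 0.1), scene.truth


@pytest.fixture
def noisy_scene():
    """Default textured/noisy 60x60x40 um scene with 40 separated beads."""
    cfg = SceneConfig(width_um=60, height_um=60, depth_um=40)
    scene = generate_scene(cfg, seed=3)
    plant_beads(scene, 40, BeadSpec(), clump_fraction=0.0, seed=11)
    return scene
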