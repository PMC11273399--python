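"""Shared fixtures: a small camera and pre-rendered synthetic scenes.

The small camera keeps frames at 960 x 720 so per-test rendering and
morphology stay fast; the full-frame default (1920 x 1080) is exercised in
the end-to-end acceptance test.
"""

import numpy as np
import pytest

from pigmorph.synthetic import (
    CameraConfig,
    CurvatureDistribution,
    generate_dataset,
    sample_biometry,
)


@pytest.fixture(scope="session")
def small_camera() -> CameraConfig:
    return CameraConfig(
        height_above_ground=145.0, focal_scale=260.0, image_width=960, image_height=720
    )


@pytest.fixture(scope="session")
def herd():
    return sample_biometry(8, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_camera):
    """12 pigs x 4 frames with default bending; used across stage tests."""
    scenes, biometry = generate_dataset(
        n_pigs=12,
        frames_per_pig=4,
        camera=small_camera,
        curvature=CurvatureDistribution(sd=0.004),
        seed=5,
    )
    return scenes, biometry


@pytest.fixture(scope="session")
def random_blob():
    """A seeded irregular 8-connected blob on a 120x140 grid."""
    from scipy import ndimage

    rng = np.random.default_rng(42)
    m = ndimage.binary_dilation(rng.random((120, 140)) > 0.997, iterations=8)
    labels, n = ndimage.label(m, structure=np.ones((3, 3), bool))
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)
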