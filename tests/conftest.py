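"""Shared fixtures: worked transform matrices and rendered synthetic images.

All image fixtures are generated at test time by the package's own renderer;
nothing is read from disk.
"""

import numpy as np
import pytest

from anchorreg import (
    AffineParams,
    DetectionConfig,
    RegistrationConfig,
    make_lattice_model,
)
from anchorreg.transforms import TransformMatrix
from anchorreg.validation import (
    HomographyMagnitude,
    random_homography,
    render_fixture,
)

# homography worked through by hand in the docs: maps (100, 100) -> (62.5, 81.25)
FIG_H = np.array(
    [[0.8, 0.2, 0.0], [0.1, 1.2, 0.0], [0.005, 0.001, 1.0]]
)


@pytest.fixture
def worked_homography() -> TransformMatrix:
    return TransformMatrix(FIG_H, kind="homography")


@pytest.fixture(scope="session")
def lattice_scene():
    """A 5x5 unit lattice rendered at 40 px/unit under a known mild
    homography, with ground truth; SNR 20."""
    model = make_lattice_model(5, 5)
    rng = np.random.default_rng(3)
    place = np.array([[40.0, 0, 50], [0, 40.0, 50], [0, 0, 1]])
    pert = random_homography(
        rng, HomographyMagnitude(0.03, 0.03, 0.01, 5.0, 2e-5), extent=200
    )
    H_true = TransformMatrix(pert.m @ place)
    img, gt = render_fixture(model, H_true, shape=(300, 300), snr=20, seed=1)
    return {"model": model, "H_true": H_true, "img": img, "gt": gt}


@pytest.fixture(scope="session")
def lattice_registration_config() -> RegistrationConfig:
    return RegistrationConfig(
        affine=AffineParams(s_x=40, s_y=40),
        detection=DetectionConfig(blur_sigma=1.0, min_separation=10),
    )
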