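import numpy as np
import pytest

from phenoplane.fiducial import PlaneHomography
from phenoplane.synthetic_scenes import render_scene, trait_scene


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def identity_homography(scale_cm_per_px: float = 1.0) -> PlaneHomography:
    """Pure-scaling pixel-to-cm calibration used by the arithmetic tests."""
    s = scale_cm_per_px
    return PlaneHomography(np.diag([s, s, 1.0]), s)


@pytest.fixture(scope="session")
def rendered_scenes():
    """One rendered scene + ground truth per trait, shared across tests."""
    gen = np.random.default_rng(2024)
    out = {}
    for trait in ("CD", "PH", "PL", "LA", "FlA", "FrA"):
        spec = trait_scene(trait, gen)
        out[trait] = render_scene(spec)
    return out
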