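import numpy as np
import pytest
from hypothesis import settings

from cmspose.landmarks import Landmark, LandmarkSet, MovementTask
from cmspose.synthetic import generate_posture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture()
def ir_set():
    """A clean 3D internal-rotation landmark set (class 3 template)."""
    return generate_posture(MovementTask.internal_rotation, 3, noise_sd=0.0, seed=0)


@pytest.fixture()
def noisy_ir_set():
    return generate_posture(MovementTask.internal_rotation, 3, noise_sd=0.02, seed=1)


def make_set(coords: dict, task=MovementTask.internal_rotation, side="right", vis=None):
    """Build a LandmarkSet from name -> (x, y[, z]) with visibility 1."""
    vis = vis or {}
    lms = {}
    for name, xyz in coords.items():
        z = xyz[2] if len(xyz) == 3 else None
        lms[name] = Landmark(xyz[0], xyz[1], z, vis.get(name, 1.0))
    return LandmarkSet(lms, task, side)
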