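import numpy as np
import pytest

from iomorph import PipelineConfig, estimate_bone_axis
from iomorph.phantom import PhantomTruth, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Canonical-frame phantom at the cadaveric study magnitudes."""
    return make_phantom(PhantomTruth(), mesh_resolution=2.0, seed=0)


@pytest.fixture(scope="session")
def default_axes(default_phantom):
    res = default_phantom
    radius_axis = estimate_bone_axis(res.radius, res.distal_hints["radius"])
    ulna_axis = estimate_bone_axis(res.ulna, res.distal_hints["ulna"])
    return radius_axis, ulna_axis


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
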