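import numpy as np
import pytest

from microphase.core import LengthDistribution
from microphase.synthetic import make_aster_volume, make_sphere_mesh


@pytest.fixture(scope="session")
def length_law():
    """The measured filament polydispersity: log-normal M=1.4, S=0.6."""
    return LengthDistribution(log_mu=1.4, log_sigma=0.6)


@pytest.fixture(scope="session")
def aster(length_law):
    """A medium-sized synthetic aster shared by read-only tests."""
    mt, k4, gt = make_aster_volume(
        n_filaments=2000, core_sigma=1.0, length_law=length_law,
        shape=(80, 80, 80), voxel_size=0.5, psf_sigma=0.2, seed=11,
    )
    return mt, k4, gt


@pytest.fixture(scope="session")
def icosphere():
    """Fine unit-test sphere mesh, R = 10 um."""
    return make_sphere_mesh(10.0, refinement=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
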