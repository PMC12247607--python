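import numpy as np
import pytest

from mrcdi import (
    ConductivityVector,
    build_phantom,
    default_spec,
    montage_ap,
    montage_rl,
    simulate_montage,
)
from mrcdi.grid import GridGeometry


@pytest.fixture(scope="session")
def small_spec():
    """32^3 at 6 mm: spans the default head with >=1-voxel shells."""
    return default_spec((32, 32, 32), 6.0)


@pytest.fixture(scope="session")
def small_vol(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def tiny_grid():
    return GridGeometry.centered(16, 4.0)


@pytest.fixture(scope="session")
def rl_forward(small_vol):
    """Ground-truth forward solution for the RL montage (phi, J, bz)."""
    return simulate_montage(small_vol, ConductivityVector.ground_truth(), montage_rl())


@pytest.fixture(scope="session")
def ap_forward(small_vol):
    return simulate_montage(small_vol, ConductivityVector.ground_truth(), montage_ap())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
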