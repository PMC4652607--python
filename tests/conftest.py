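import numpy as np
import pytest

from osteomorph.core import VoxelVolume
from osteomorph.synthetic_data import make_porous_shell


@pytest.fixture(scope="session")
def porous_shell():
    """One seeded porous cortical slab shared by segmentation/porosity tests."""
    vol, manifest, specs = make_porous_shell(seed=0)
    return vol, manifest, specs


@pytest.fixture()
def binary_volume():
    """Factory wrapping a boolean array as a binary VoxelVolume."""
    def make(mask, voxel_size=1.0):
        return VoxelVolume(np.asarray(mask).astype(np.uint8), voxel_size,
                           is_binary=True)
    return make
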