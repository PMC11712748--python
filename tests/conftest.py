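import numpy as np
import pytest

from hnplan.phantom import PhantomSpec, generate_phantom
from hnplan.volumes import Role, StructureSet, VoxelVolume

#: Coarse spec for pipeline-level tests: same anatomy extents, 5 mm voxels.
COARSE_SPEC = PhantomSpec(grid_shape=(48, 48, 48), spacing_mm=(5.0, 5.0, 5.0))

#: Medium spec for dosimetric tradeoff tests: 3.75 mm voxels.
MEDIUM_SPEC = PhantomSpec(grid_shape=(64, 64, 64), spacing_mm=(3.75, 3.75, 3.75))


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def coarse_phantom():
    return generate_phantom(COARSE_SPEC)


@pytest.fixture(scope="session")
def medium_phantom():
    return generate_phantom(MEDIUM_SPEC)


def make_volume(values, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), unit="HU"):
    return VoxelVolume(np.asarray(values, float), spacing, origin, unit=unit)


def water_volume(shape=(16, 16, 16), spacing=(2.5, 2.5, 2.5), origin=None, hu=0.0):
    """Homogeneous water-equivalent block, grid centred on the origin in x/y/z."""
    if origin is None:
        origin = tuple(-(n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    return VoxelVolume(np.full(shape, hu), spacing, origin, unit="HU")


def single_structure_set(volume, mask, name="ptv", rx=44.0):
    s = StructureSet(volume)
    s.add("body", np.ones(volume.shape, bool), Role.BODY)
    s.add(name, mask, Role.PTV, rx_gy=rx)
    return s
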