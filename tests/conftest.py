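import numpy as np
import pytest

from mapres.boxes import BandSpec
from mapres.map_io import DensityMap, Mask
from mapres.spectral import FilterBankSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_map(rng):
    """A 24^3 random map at 1.0 A/voxel."""
    return DensityMap(data=rng.standard_normal((24, 24, 24)).astype(np.float32), voxel_size=1.0)


@pytest.fixture()
def full_mask(small_map):
    return Mask(data=np.ones(small_map.shape, np.uint8))


@pytest.fixture()
def coarse_band():
    """A cheap band for unit tests: 1.0 A/voxel, cutoffs 3..12 step 1."""
    return BandSpec(voxel_size=1.0, bank=FilterBankSpec(3.0, 12.0, 1.0))


def unit_cubes(rng, n):
    cubes = rng.standard_normal((n, 13, 13, 13)).astype(np.float32)
    cubes /= np.linalg.norm(cubes.reshape(n, -1), axis=1)[:, None, None, None]
    return cubes
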