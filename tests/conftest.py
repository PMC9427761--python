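import numpy as np
import pytest

from ringomics.cohort import CohortConfig, generate_case
from ringomics.geometry import BinaryMask, build_peritumoral_ring, exclusion_from_hu


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_cases=6, grid_shape=(40, 40, 40), seed=11)


@pytest.fixture(scope="session")
def sample_case(small_config):
    return generate_case(small_config, "High", "fixture_case", seed=123)


@pytest.fixture(scope="session")
def sample_rois(sample_case):
    excl = exclusion_from_hu(sample_case.volume)
    return build_peritumoral_ring(sample_case.tumor_mask, exclusion=excl)


def sphere_mask(radius_mm: float, spacing: float, pad_mm: float = 4.0) -> BinaryMask:
    """Voxelized sphere centred on the grid."""
    half = radius_mm + pad_mm
    n = int(np.ceil(2 * half / spacing)) + 1
    coords = (np.arange(n) - (n - 1) / 2) * spacing
    xx, yy, zz = np.meshgrid(coords, coords, coords, indexing="ij")
    vox = xx**2 + yy**2 + zz**2 <= radius_mm**2
    return BinaryMask(vox, (spacing,) * 3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
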