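import numpy as np
import pytest

from contourdose import StructureMask, VoxelGrid, make_grid


@pytest.fixture
def unit_grid():
    """10x10x10 grid at 1 mm isotropic spacing, origin at zero."""
    return make_grid((10, 10, 10), (1.0, 1.0, 1.0))


@pytest.fixture
def grid21():
    """21 voxels per axis at 1 mm; fits a 10 mm-radius sphere centred at 10."""
    return make_grid((21, 21, 21), (1.0, 1.0, 1.0))


def random_blob(grid: VoxelGrid, rng: np.random.Generator, name: str = "blob",
                max_spheres: int = 3) -> StructureMask:
    """Union of a few random spheres — a generic irregular test mask."""
    shape = np.asarray(grid.shape)
    spacing = np.asarray(grid.spacing)
    extent = shape * spacing
    voxels = np.zeros(grid.shape, dtype=bool)
    x, y, z = grid.coordinate_arrays()
    for _ in range(rng.integers(1, max_spheres + 1)):
        c = np.asarray(grid.origin) + extent * rng.uniform(0.25, 0.75, 3)
        r = rng.uniform(1.5, 0.25 * extent.min())
        voxels |= (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r ** 2
    if not voxels.any():
        voxels[tuple(shape // 2)] = True
    return StructureMask(grid, voxels, name)


@pytest.fixture
def make_blob():
    return random_blob
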