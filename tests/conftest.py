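import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from tmtvbench import PETVolume, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def grid2mm():
    return VoxelGrid((10, 10, 10), (2.0, 2.0, 2.0))


@pytest.fixture
def two_sphere_pet():
    """Noise-free 4 mm grid with one ~10 cm^3 and one ~2 cm^3 SUV-8 sphere
    on an SUV-1 background."""
    grid = VoxelGrid((40, 40, 40), (4.0, 4.0, 4.0))
    x = (4.0 * np.arange(40))[:, None, None]
    y = (4.0 * np.arange(40))[None, :, None]
    z = (4.0 * np.arange(40))[None, None, :]
    values = np.full(grid.shape, 1.0, dtype=np.float32)
    big = (x - 60) ** 2 + (y - 60) ** 2 + (z - 60) ** 2 <= 13.4**2  # ~10 cm^3
    small = (x - 120) ** 2 + (y - 120) ** 2 + (z - 120) ** 2 <= 7.8**2  # ~2 cm^3
    values[big] = 8.0
    values[small] = 8.0
    pet = PETVolume(grid, values)
    return pet, big, small
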