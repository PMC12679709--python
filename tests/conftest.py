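import numpy as np
import pytest

from lesionnet.synthetic import SyntheticCohortSpec, default_grid
from lesionnet.volumes import BinaryMask, ScalarMap, VolumeGrid


@pytest.fixture
def unit_grid():
    """4x4x4 grid with identity affine."""
    return VolumeGrid((4, 4, 4), np.eye(4), "unit")


@pytest.fixture
def small_spec():
    """Desk-scale synthetic study conditions shrunk for unit tests."""
    return SyntheticCohortSpec(
        n_subjects=8,
        n_timepoints=60,
        grid=default_grid(16),
        seed=11,
    )


@pytest.fixture
def default_spec():
    """The generator's default study conditions (20 subjects, 24^3 grid)."""
    return SyntheticCohortSpec(seed=11)


def full_mask(grid: VolumeGrid) -> BinaryMask:
    return BinaryMask(grid, np.ones(grid.shape, bool))


def scalar(grid: VolumeGrid, values) -> ScalarMap:
    return ScalarMap(grid, np.asarray(values, dtype=float))
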