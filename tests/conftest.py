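import numpy as np
import pytest

from y90voxdose import (
    Compartment,
    PETAcqParams,
    PhantomSpec,
    VOIMask,
    VoxelGrid,
    build_phantom,
)

VOXEL = (2.73, 2.73, 3.27)


@pytest.fixture(scope="session")
def insert_phantom():
    """Cylindrical lesion insert (d=28.5, h=30 mm) in a warm background."""
    spec = PhantomSpec(
        shape=(24, 24, 20),
        voxel_size_mm=VOXEL,
        compartments=[
            Compartment("insert", "cylinder", (32.76, 32.76, 32.7), (28.5, 30.0), 5.5e6)
        ],
        background_bq_ml=0.89e6,
    )
    activity, masks = build_phantom(spec)
    return spec, activity, masks


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_grid(values, voxel=VOXEL, unit="Bq/mL"):
    return VoxelGrid(np.asarray(values, dtype=float), voxel, unit)


def full_mask(grid):
    return VOIMask(np.ones(grid.shape, dtype=bool), grid.voxel_size_mm)
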