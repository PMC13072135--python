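import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from polscope import TankGeometry, Trajectory3D


@pytest.fixture
def geometry() -> TankGeometry:
    return TankGeometry()


@pytest.fixture
def random_trajectory_factory(geometry):
    """Uniform random in-tank trajectories (not from the movement model),
    for oracle-equivalence checks."""

    def make(seed: int, n_frames: int = 200, frame_interval: float = 1 / 30):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0.0, geometry.extents, size=(n_frames, 3))
        times = np.arange(n_frames) * frame_interval
        return Trajectory3D(times=times, positions=pos, geometry=geometry,
                            fish_id=f"rand{seed}")

    return make


def voxel_center(ix: int, iy: int, iz: int, geometry: TankGeometry) -> tuple:
    g = geometry.grid_divisions_per_axis
    cell = geometry.extents / g
    return (
        (ix + 0.5) * cell[0],
        (iy + 0.5) * cell[1],
        (iz + 0.5) * cell[2],
    )


@pytest.fixture
def voxel_center_fn(geometry):
    return lambda ix, iy, iz: voxel_center(ix, iy, iz, geometry)
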