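import numpy as np
import pytest

from pirview import SensorGrid
from pirview import sensor_sim as sim


@pytest.fixture(scope="session")
def grid() -> SensorGrid:
    return SensorGrid()


@pytest.fixture(scope="session")
def walk_fall_stream(grid):
    """One seeded walk-then-fall round at the default 20 Hz."""
    return sim.simulate_stream(grid, sim.walk_then_fall_script(), 20, seed=1)


def make_stream(frames, rate_H=20, grid=SensorGrid()):
    """Wrap a (T, 4, 5) or (T, 20) binary array as a SensorStream."""
    frames = np.asarray(frames, dtype=np.uint8)
    if frames.ndim == 2:
        frames = frames.reshape(-1, grid.n_rows, grid.n_cols)
    labels = np.full(frames.shape[0], "motionless", dtype=object)
    return sim.SensorStream(rate_H=rate_H, frames=frames, labels=labels, grid=grid)
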