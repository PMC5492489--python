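import numpy as np
import pytest

from bedwatch.io import GRID_COLS, GRID_ROWS, FrameSequence, ThermalFrame
from bedwatch.simulate import SceneConfig, bed_mask


@pytest.fixture
def scene():
    return SceneConfig()


@pytest.fixture
def bed(scene):
    return bed_mask(scene)


def make_frame(index=0, value=420, distance=180, grid=None):
    if grid is None:
        grid = np.full((GRID_ROWS, GRID_COLS), value, dtype=np.int64)
    return ThermalFrame(index=index, grid=np.asarray(grid, dtype=np.int64), distance_cm=distance)


def make_sequence(grids, distance=180, start=0):
    return FrameSequence(
        [make_frame(index=start + i, grid=g, distance=distance) for i, g in enumerate(grids)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
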