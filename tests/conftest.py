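import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from gm3d.depth_reconstruction import Trajectory3D
from gm3d.formats_io import POI_NAMES, default_camera


@pytest.fixture
def camera():
    return default_camera()


def make_trajectory(positions: np.ndarray, rate_hz: float = 30.0,
                    t0_ms: float = 0.0) -> Trajectory3D:
    """Wrap an (n, 6, 3) mm position array as a fully valid trajectory."""
    n = positions.shape[0]
    times = t0_ms + 1000.0 / rate_hz * np.arange(n)
    return Trajectory3D(
        xyz=np.asarray(positions, dtype=float),
        slot_times_ms=times,
        reason=np.zeros((n, len(POI_NAMES)), dtype=np.int8),
        filled=np.zeros((n, len(POI_NAMES)), dtype=bool),
        usable=np.ones(len(POI_NAMES), dtype=bool),
    )


@pytest.fixture
def make_traj():
    return make_trajectory
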