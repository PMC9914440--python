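import numpy as np
import pytest

from memdyn.trajectories import Trajectory


def make_traj(xy, frames=None, tau=0.030, pid=0):
    xy = np.asarray(xy, dtype=float)
    if frames is None:
        frames = np.arange(len(xy))
    return Trajectory(particle_id=pid, frames=frames, xy=xy, frame_interval=tau)


@pytest.fixture
def traj_factory():
    return make_traj


@pytest.fixture
def square_mask():
    """64×64 mask with a 3×3 block of on-pixels centered at (32, 32)."""
    m = np.zeros((64, 64), dtype=bool)
    m[31:34, 31:34] = True
    return m
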