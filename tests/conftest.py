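import numpy as np
import pytest

from fbindex import TankGeometry, Trajectory
from fbindex.trajectory_io import INVALID, OBSERVED


@pytest.fixture
def geometry():
    return TankGeometry()


def make_traj(positions, dt=0.2, geometry=None, valid=None, mode="3d"):
    """Build a uniform trajectory from an (n, 2|3) position array."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    t = np.arange(n) * dt
    geometry = geometry or TankGeometry()
    if positions.shape[1] == 3:
        x, y, z = positions.T
    else:
        x, z = positions.T
        y = None
    if valid is not None:
        valid = np.asarray(valid, dtype=np.uint8)
    return Trajectory(t=t, x=x, y=y, z=z, valid=valid, geometry=geometry,
                      rate_hz=1.0 / dt)


def random_segment(rng, geometry=None, max_samples=1000, min_samples=150):
    """Random bounded walk with random invalid runs, for oracle comparison."""
    geometry = geometry or TankGeometry()
    n = int(rng.integers(min_samples, max_samples + 1))
    dt = float(rng.choice([0.04, 0.1, 0.2]))
    dims = 3 if rng.random() < 0.8 else 2
    extents = ((geometry.width_cm, geometry.depth_cm, geometry.height_cm)
               if dims == 3 else (geometry.width_cm, geometry.height_cm))
    # correlated jitters plus occasional jumps so speeds span the thresholds
    steps = rng.normal(0, 0.6, size=(n, dims))
    jumps = rng.random(n) < 0.05
    steps[jumps] *= 8
    pos = np.cumsum(steps, axis=0)
    for k, e in enumerate(extents):
        r = np.mod(pos[:, k] + 0.5 * e, 2 * e)
        pos[:, k] = np.where(r > e, 2 * e - r, r)
    valid = np.full(n, OBSERVED, dtype=np.uint8)
    # a few invalid runs
    for _ in range(int(rng.integers(0, 4))):
        start = int(rng.integers(0, n - 5))
        length = int(rng.integers(1, 12))
        valid[start:start + length] = INVALID
    valid[: 3] = OBSERVED  # keep a valid run at the start
    if dims == 3:
        nan_mask = (valid == INVALID) & (rng.random(n) < 0.5)
        pos[nan_mask] = np.nan
    return make_traj(pos, dt=dt, geometry=geometry, valid=valid)
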