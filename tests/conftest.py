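import numpy as np
import pytest

from endotrack import Ensemble, Trajectory
from endotrack import simulate as sim_mod


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ballistic():
    """x = v·t with v = 1 μm/s, stationary in y."""
    dt = 0.05
    n = 200
    return Trajectory("ballistic", dt, np.arange(n) * dt, np.zeros(n))


@pytest.fixture
def stationary():
    return Trajectory("still", 0.05, np.zeros(50), np.zeros(50))


def brownian_trajectory(tid, n_steps, dt, D, rng):
    step = np.sqrt(2 * D * dt)
    xs = np.concatenate([[0.0], np.cumsum(rng.normal(0, step, n_steps))])
    ys = np.concatenate([[0.0], np.cumsum(rng.normal(0, step, n_steps))])
    return Trajectory(tid, dt, xs, ys)


@pytest.fixture
def brownian_ensemble(rng):
    """200 Brownian trajectories, D = 1, dt = 0.05 s, 100 steps."""
    trajs = [brownian_trajectory(f"bm{i}", 100, 0.05, 1.0, rng) for i in range(200)]
    return Ensemble(trajs, meta={"source": "test"})


@pytest.fixture
def fbm_ensemble():
    """300 noiseless constant-H FBM trajectories (H = 0.25, D = 1)."""
    from endotrack.validation import fbm_constant_ensemble

    return fbm_constant_ensemble(H=0.25, n_traj=300, n_steps=256, dt=0.05,
                                 D=1.0, seed=42)


def random_walk_trajectory(tid, n, dt, rng):
    xs = np.cumsum(rng.normal(size=n))
    ys = np.cumsum(rng.normal(size=n))
    return Trajectory(tid, dt, xs, ys)
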