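import numpy as np
import pytest

from gridcan.drive import Trajectory, synth_trajectory
from gridcan.engine import SimConfig, run_simulation
from gridcan.network import build_network


@pytest.fixture(scope="session")
def small_network():
    """Quarter-size intermediate-scale network shared across tests."""
    return build_network("intermediate", seed=1, grid_side=20)


@pytest.fixture(scope="session")
def short_trajectory():
    return synth_trajectory(20.0, seed=7)


@pytest.fixture(scope="session")
def stationary_trajectory():
    n = int(10.0 / 0.02)
    return Trajectory(
        t=np.arange(n) * 0.02,
        x=np.full(n, 22.5),
        y=np.full(n, 22.5),
        arena=(45.0, 45.0),
    )


@pytest.fixture(scope="session")
def stationary_run(small_network, stationary_trajectory):
    """10 s stationary-animal simulation with default drive, reused by
    the engine and pattern tests."""
    cfg = SimConfig(settle_s=2.0, g_place=0.0, g_speed=0.0)
    spikes, mon = run_simulation(
        small_network, stationary_trajectory, cfg, seed=3,
        monitor_neurons={"MEC LII Stellate": [210]},
    )
    return spikes, mon
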