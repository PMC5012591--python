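import numpy as np
import pytest

from tumblekit.simulate import (
    MotorParams,
    SwimParams,
    Trajectory,
    simulate_cells,
    yp_for_bias,
)


@pytest.fixture(scope="session")
def motor():
    return MotorParams()


@pytest.fixture(scope="session")
def noisy_swim():
    """Swim parameters with tracking-like localization noise."""
    return SwimParams(loc_noise=0.1)


@pytest.fixture(scope="session")
def small_panel(noisy_swim):
    """Small multi-bias panel of simulated trajectories (with truth labels)."""
    biases = (0.1, 0.25, 0.4)
    panel = {}
    for b in biases:
        panel[b] = simulate_cells(
            yp_for_bias(b), 12, 120.0, seed=int(1000 * b), sp=noisy_swim
        )
    return panel


@pytest.fixture()
def straight_trajectory():
    """Uniform straight-line motion: 2 um steps at 0.1 s -> 20 um/s."""
    t = np.arange(50) * 0.1
    return Trajectory(t=t, x=2.0 * np.arange(50), y=np.zeros(50), cell_id="straight")


@pytest.fixture()
def circle_trajectory():
    """Uniform circular motion, radius 10 um, angular rate 0.5 rad/s."""
    t = np.arange(600) * 0.1
    return Trajectory(
        t=t, x=10 * np.cos(0.5 * t), y=10 * np.sin(0.5 * t), cell_id="circle"
    )
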