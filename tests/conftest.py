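import numpy as np
import pytest

from armcycle.simulate import SimulationConfig, simulate_crank_cycling


@pytest.fixture(scope="session")
def short_config() -> SimulationConfig:
    """30 s at 60 cycles/min, controlled zero phase offset, noiseless."""
    return SimulationConfig(cadence_profile=60.0, duration=30.0,
                            elbow_shoulder_phase_offset=0.0, seed=11)


@pytest.fixture(scope="session")
def short_trajectory(short_config):
    return simulate_crank_cycling(short_config)


@pytest.fixture(scope="session")
def natural_trajectory():
    """Pure inverse-kinematics coupling: hand exactly on the crank circle."""
    cfg = SimulationConfig(cadence_profile=60.0, duration=30.0,
                           elbow_shoulder_phase_offset=None, seed=11)
    return simulate_crank_cycling(cfg)


@pytest.fixture()
def sinusoid_angles():
    """Analytic shoulder/elbow sinusoids at 1 Hz, 100 Hz sampling, 30 s."""
    fs = 100.0
    t = np.arange(3000) / fs
    shoulder = 105.0 + 22.0 * np.sin(2 * np.pi * t)
    elbow = 80.0 + 40.0 * np.sin(2 * np.pi * t)
    return t, shoulder, elbow, fs
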