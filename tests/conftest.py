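import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import magrheo as m

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example_cal():
    """Worked-example calibration constants used throughout the hand
    calculations: F0 = 1e5, (c1, c2, c3) = (-3, 2, -1.5)."""
    return m.CalibrationModel(F0=1e5, c1=-3.0, c2=2.0, c3=-1.5,
                              current_range=(0.01, 3.0),
                              distance_range=(10.0, 150.0),
                              saturation_current=1.0)


@pytest.fixture(scope="session")
def drag_truth():
    """Ground-truth calibration for drag-simulation recovery: nN-scale
    forces that grow with current across the simulated distance range."""
    return m.CalibrationModel(F0=700.0, c1=-4.0, c2=1.0, c3=1.0,
                              current_range=(0.2, 1.0),
                              distance_range=(40.0, 160.0),
                              saturation_current=1.0)


@pytest.fixture
def quiet_cfg():
    return m.SimulationConfig()


@pytest.fixture(scope="session")
def cell_material():
    """A soft-cell-like material: stiffness 300 Pa, fluidity 0.45."""
    return m.MaterialModel("power_law", J0=1.0 / 300.0, beta=0.45)
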