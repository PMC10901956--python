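import numpy as np
import pytest

from osteoadapt import beam, mechanostat, synthetic
from osteoadapt.contours import ENDOSTEAL, PERIOSTEAL, circle_contour


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def circle_pair():
    """Concentric circular annulus: R = 600, r = 400 μm, 500 points."""
    peri = circle_contour(600.0, 500, surface=PERIOSTEAL)
    endo = circle_contour(400.0, 500, surface=ENDOSTEAL)
    return peri, endo


@pytest.fixture(scope="session")
def baseline_pair():
    """Registered tibia-like baseline at the default study geometry."""
    return synthetic.make_baseline_geometry(synthetic.GeometrySpec())


@pytest.fixture(scope="session")
def schedule():
    return mechanostat.SimulationSchedule()


@pytest.fixture(scope="session")
def calibration_load():
    return beam.LoadCase(F=10.0, p_F=synthetic.DEFAULT_LOAD_POINT_UM)
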