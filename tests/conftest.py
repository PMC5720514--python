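import numpy as np
import pytest

from eadsim import build_params
from eadsim.tissue import StimEvent, build_grid, run_simulation


@pytest.fixture(scope="session")
def default_params():
    return build_params(1.0, 1.0)


@pytest.fixture(scope="session")
def cable_grid():
    """The calibration cable: 8 cm, dx = 0.04 cm (200 nodes)."""
    return build_grid("cable", 8.0, 0.04)


@pytest.fixture(scope="session")
def sqrt_d_cvs(default_params):
    """Conduction velocity at D/4, D, 4D on a resolved cable.

    dx = 0.005 cm so the narrowest front (at D/4) spans several nodes, and
    a CFL-safe dt per diffusivity.  Shared: this is the most expensive of
    the calibration measurements.
    """
    from eadsim.metrics import measure_cv
    from eadsim.tissue import conductivity_from_fibers

    grid = build_grid("cable", 8.0, 0.005)
    cvs = {}
    for mult, dt in ((0.25, 0.005), (1.0, 0.005), (4.0, 0.002)):
        cond = conductivity_from_fibers(grid, dl=0.00154 * mult)
        ev = StimEvent(nodes=np.arange(16), start=5.0, duration=1.0)
        res = run_simulation(grid, default_params, 400.0, cond=cond, dt=dt,
                             events=(ev,), sample_dt=0.1)
        cvs[mult] = measure_cv(res.movie, 2.0, 6.0)
    return cvs


@pytest.fixture(scope="session")
def cable_wave_movie(cable_grid, default_params):
    """A single planar wave on the calibration cable (shared by CV tests)."""
    ev = StimEvent(nodes=np.arange(2), start=5.0, duration=1.0)
    res = run_simulation(cable_grid, default_params, 150.0, events=(ev,),
                         sample_dt=0.1)
    return res.movie
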