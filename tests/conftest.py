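import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cbct4d as c
from cbct4d.phantom import analytic_dvf
from cbct4d.pipeline import desk_geometry, desk_grid, small_geometry, small_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return desk_grid()


@pytest.fixture(scope="session")
def geometry():
    return desk_geometry()


@pytest.fixture(scope="session")
def phantom():
    return c.build_phantom(seed=1)


@pytest.fixture(scope="session")
def gt4d(phantom, grid):
    return c.generate_4dct(phantom, grid)


@pytest.fixture(scope="session")
def rois(phantom, grid):
    return c.auto_rois(phantom, grid)


def _static_phantom(seed=0):
    cfg = dataclasses.replace(
        c.PhantomConfig(), diaphragm_amplitude=0.0,
        tumor_amplitude=(0.0, 0.0, 0.0),
    )
    return c.Phantom4D(cfg, seed)


@pytest.fixture(scope="session")
def static_phantom():
    return _static_phantom()


@pytest.fixture(scope="session")
def static_bundle(static_phantom, grid, geometry):
    """Zero-motion phantom with a rapid-protocol scan at desk scale.

    Shared by the FDK accuracy and motion-compensation algebra tests."""
    g4 = c.generate_4dct(static_phantom, grid)
    pset = c.simulate_scan(g4, geometry, c.RAPID)
    return {"phantom": static_phantom, "gt4d": g4, "rapid": pset}


@pytest.fixture(scope="session")
def moving_bundle(phantom, gt4d, grid, geometry):
    """Default breathing phantom, rapid scan, perfect planning DVFs."""
    pset = c.simulate_scan(gt4d, geometry, c.RAPID)
    dvfs = [analytic_dvf(phantom, p, 0, grid) for p in range(10)]
    return {"phantom": phantom, "gt4d": gt4d, "rapid": pset, "dvfs": dvfs}


@pytest.fixture(scope="session")
def cohort10():
    """The seeded desk-scale study cohort (n=10)."""
    return c.run_cohort(c.StudyConfig(n_patients=10, seed=0))


@pytest.fixture(scope="session")
def small_study_cfg():
    return c.StudyConfig(n_patients=1, seed=7, preset="small")
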