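import numpy as np
import pytest

from hemolab.geometry import JunctionGeometry, build_junction
from hemolab.solver import BoundarySpec, FluidProperties
from hemolab.waveforms import CycleStructure, WaveformSpec


@pytest.fixture(scope="session")
def cycles():
    return CycleStructure(heart_period=0.6, beats_per_breath=4)


@pytest.fixture(scope="session")
def ivc_spec():
    return WaveformSpec(
        port="IVC", mean_level=0.3,
        cardiac_harmonics=((1, 0.10, 0.0), (2, 0.05, 0.8)),
        resp_mod_depth=0.25,
    )


@pytest.fixture(scope="session")
def props():
    return FluidProperties()


@pytest.fixture(scope="session")
def coarse_junction():
    """9 mm junction at 10 cells across: the cheap solver test bed."""
    return build_junction(JunctionGeometry(), h=0.0009)


@pytest.fixture(scope="session")
def steady_junction_run(coarse_junction, props):
    """A short steady-inflow junction solve shared across metric tests."""
    from hemolab.solver import run_steady

    bc = BoundarySpec(
        inlets={"IVC": (0.15, "parabolic"), "SVC": (0.15, "parabolic")},
        outlets={"LPA": 0.0, "RPA": 0.0},
    )
    state = run_steady(coarse_junction, bc, props, steady_tol=1e-5,
                       max_time=4.0)
    return state, coarse_junction, bc
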