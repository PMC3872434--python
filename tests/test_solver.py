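"""Solver verification: quiescence, Poiseuille, conservation, dimensionless ops."""

import numpy as np
import pytest

from hemolab.benchmarks import poiseuille_case
from hemolab.geometry import JunctionGeometry, build_channel, build_junction
from hemolab.metrics import port_fluxes
from hemolab.solver import (BoundarySpec, FluidProperties, FlowState,
                            LaminarReport, Simulator, SolverConfig,
                            check_laminar, compute_reynolds, courant_number,
                            run, select_timestep)


def test_quiescent_fluid_stays_quiescent(coarse_junction, props):
    bc = BoundarySpec(inlets={"IVC": (0.0, "flat"), "SVC": (0.0, "flat")},
                      outlets={"LPA": 0.0, "RPA": 0.0})
    sim = Simulator(coarse_junction, bc, props, SolverConfig())
    for _ in range(5):
        sim.step(1e-3)
    assert sim.max_speed() == 0.0
    assert np.all(sim.p == 0.0)


def test_poiseuille_coarse_channel(props):
    """Steady plane Poiseuille at 10 cells across: profile, dP/dx, EL, mass."""
    rep = poiseuille_case(cells_across=10, steady_tol=1e-6)
    assert rep.centerline_error < 0.03
    assert rep.gradient_error < 0.05
    assert rep.el_error < 0.05
    assert rep.mass_imbalance < 1e-12
    assert rep.divergence_max < 1e-8


def test_poiseuille_error_shrinks_under_refinement(props):
    coarse = poiseuille_case(cells_across=10, steady_tol=1e-6)
    fine = poiseuille_case(cells_across=20, steady_tol=1e-6)
    assert fine.wss_error < coarse.wss_error
    assert fine.centerline_error < coarse.centerline_error + 1e-3


def test_junction_mass_balance_every_step(coarse_junction, props):
    bc = BoundarySpec(inlets={"IVC": (0.15, "parabolic"),
                              "SVC": (0.15, "parabolic")},
                      outlets={"LPA": 0.0, "RPA": 0.0})
    cfg = SolverConfig(n_cycles=2, discard_cycles=1, snapshots_per_cycle=10)
    res = run(coarse_junction, bc, props, cfg, cycle_period=0.15)
    for snap in res.snapshots:
        fx = port_fluxes(snap, coarse_junction, props)
        q_in = sum(f.Q for f in fx if f.kind == "inlet")
        q_out = sum(f.Q for f in fx if f.kind == "outlet")
        qmax = max(abs(f.Q) for f in fx)
        if qmax > 0:
            assert abs(q_in - q_out) < 1e-8 * qmax
    assert res.diagnostics["div_max"] < 1e-5


def test_steady_bc_cycle_to_cycle_flux_settles(coarse_junction, props):
    bc = BoundarySpec(inlets={"IVC": (0.1, "parabolic"),
                              "SVC": (0.1, "parabolic")},
                      outlets={"LPA": 0.0, "RPA": 0.0})
    cfg = SolverConfig(n_cycles=6, discard_cycles=1, snapshots_per_cycle=4)
    res = run(coarse_junction, bc, props, cfg, cycle_period=0.4)
    per = res.diagnostics["cycle_periodicity"]
    assert per[-1] < 0.02  # steady limit: late cycles nearly identical


def test_energy_inequality_steady_channel(props):
    """Viscous dissipation is non-negative: total-pressure influx bounds efflux."""
    from hemolab.solver import run_steady

    grid = build_channel(0.009, 0.045, 0.0009, depth=0.009)
    bc = BoundarySpec(inlets={"IVC": (0.1, "parabolic")},
                      outlets={"RPA": 0.0})
    state = run_steady(grid, bc, props, steady_tol=1e-6, max_time=20.0)
    fx = {f.port: f for f in port_fluxes(state, grid, props)}
    influx = (fx["IVC"].P_mean * fx["IVC"].Q + fx["IVC"].ke_flux(props.rho))
    efflux = (fx["RPA"].P_mean * fx["RPA"].Q + fx["RPA"].ke_flux(props.rho))
    assert influx >= efflux > 0


def test_select_timestep_eq4_inversion(coarse_junction, props):
    """dt = Cr_max * h / u_mean, with the printed mean speed as a check."""
    nx, ny = coarse_junction.nx, coarse_junction.ny
    u = np.full((nx + 1, ny), 0.5)
    v = np.full((nx, ny + 1), 0.5)
    st = FlowState(u, v, np.zeros((nx, ny)), 0.0)
    grid = coarse_junction
    dt = select_timestep(st, grid, cr_max=0.5)
    assert dt == pytest.approx(0.5 * grid.h / 0.5)
    # doubling the cell size doubles dt
    from hemolab.geometry import StaggeredGrid

    grid2 = StaggeredGrid(h=2 * grid.h, fluid=grid.fluid, ports=grid.ports,
                          depth=grid.depth)
    assert select_timestep(st, grid2, cr_max=0.5) == pytest.approx(2 * dt)
    # all-zero velocity falls back to the configured fixed step
    st0 = FlowState(0 * u, 0 * v, np.zeros((nx, ny)), 0.0)
    assert select_timestep(st0, grid, 0.5, dt_fixed=1e-4) == 1e-4


def test_courant_forward_evaluation():
    """Cr for the reported mean speed at the reference step and cell size."""
    assert courant_number(0.3419, 1e-4, 0.001) == pytest.approx(0.03419)


def test_reynolds_examples(props):
    assert compute_reynolds(1.0, 1.0, FluidProperties(rho=1.0, mu=1.0)) == 1.0
    assert compute_reynolds(0.0, 1.0, props) == 0.0
    # forward evaluation reproduces the clinical-scale value: a mean speed
    # of 0.3419 m/s in a D = 8.857 mm vessel gives Re ~ 802.5
    assert compute_reynolds(0.3419, 0.008857, props) == pytest.approx(802.5, abs=0.1)


def test_check_laminar_flags():
    class MS:
        t = np.array([0.0, 0.1, 0.2])
        Re = {"IVC": np.array([800.0, 1200.0, 900.0])}

    rep = check_laminar(MS(), threshold=1000.0)
    assert not rep.laminar
    assert rep.flags == [("IVC", 0.1, 1200.0)]
    assert rep.re_max == 1200.0
    rep2 = check_laminar(MS(), threshold=1500.0)
    assert rep2.laminar
    rep3 = check_laminar(MS(), threshold=0.0)
    assert len(rep3.flags) == 3


def test_nan_detection_raises(coarse_junction, props):
    from hemolab.solver import SolverError

    bc = BoundarySpec(inlets={"IVC": (0.15, "parabolic"),
                              "SVC": (0.15, "parabolic")},
                      outlets={"LPA": 0.0, "RPA": 0.0})
    cfg = SolverConfig(cr_max=1.0, dt_fixed=0.02, n_cycles=2,
                       discard_cycles=0)  # wildly unstable on purpose
    with pytest.raises(SolverError):
        with np.errstate(all="ignore"):
            run(coarse_junction, bc, props, cfg, cycle_period=0.2)
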