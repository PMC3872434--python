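"""Analytic verification cases for the flow solver.

Plane Poiseuille flow in a straight channel checks the steady viscous
balance (centerline velocity 1.5 u_bar, pressure gradient 12 mu u_bar / w^2,
wall shear 6 mu u_bar / w) and the control-volume energy loss against
dP * Q.  A slowly oscillating channel at low Womersley number

    alpha = (w/2) sqrt(omega rho / mu)

checks the unsteady path: for alpha << 1 the profile is quasi-steady, i.e.
the instantaneous parabola of the instantaneous mean flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import build_channel
from .metrics import compute_EL, compute_WSS, port_fluxes
from .solver import (BoundarySpec, FluidProperties, Simulator, SolverConfig,
                     run_steady)
from .waveforms import Waveform

__all__ = ["poiseuille_case", "oscillatory_channel_case"]


@dataclass
class PoiseuilleReport:
    centerline_error: float       # relative, vs 1.5 u_bar
    gradient_error: float         # relative, vs 12 mu u_bar / w^2
    wss_error: float              # relative, vs 6 mu u_bar / w
    el_error: float               # relative, vs dP_analytic * Q
    mass_imbalance: float         # |Q_in - Q_out| / Q_in
    divergence_max: float

    def ok(self, tol_profile=0.02, tol_wss=0.05, tol_el=0.03) -> bool:
        return (self.centerline_error < tol_profile
                and self.gradient_error < tol_profile
                and self.wss_error < tol_wss
                and self.el_error < tol_el)


def poiseuille_case(width: float = 0.009, u_mean: float = 0.1,
                    cells_across: int = 20, length_widths: float = 6.0,
                    props: FluidProperties | None = None,
                    steady_tol: float = 1e-6) -> PoiseuilleReport:
    """Steady plane Poiseuille channel vs the analytic solution."""
    props = props or FluidProperties()
    h = width / cells_across
    length = length_widths * width
    grid = build_channel(width, length, h, depth=width)
    bc = BoundarySpec(inlets={"IVC": (u_mean, "parabolic")},
                      outlets={"RPA": 0.0})
    state = run_steady(grid, bc, props, steady_tol=steady_tol, max_time=30.0)

    # centerline velocity: maximum sampled x-velocity mid-channel
    mid = grid.nx // 2
    u_profile = state.u[mid, :]
    u_center = float(np.max(u_profile))
    centerline_error = abs(u_center - 1.5 * u_mean) / (1.5 * u_mean)

    # streamwise pressure gradient from a mid-height cell row, middle half
    jmid = grid.ny // 2
    i0, i1 = grid.nx // 4, 3 * grid.nx // 4
    x = (np.arange(i0, i1) + 0.5) * h
    slope = np.polyfit(x, state.p[i0:i1, jmid], 1)[0]
    g_exact = -12.0 * props.mu * u_mean / width**2
    gradient_error = abs(slope - g_exact) / abs(g_exact)

    # wall shear stress mid-channel
    wss = compute_WSS(state, grid, props)
    midmask = np.abs(wss.x - length / 2) < 2 * h
    tau = float(np.mean(np.abs(wss.tau[midmask])))
    tau_exact = 6.0 * props.mu * u_mean / width
    wss_error = abs(tau - tau_exact) / tau_exact

    # control-volume energy loss vs dP Q over the distance between the
    # port planes (kinetic terms cancel by symmetry)
    fx = port_fluxes(state, grid, props)
    el = compute_EL(np.array([state.t]), [fx], props).EL[0]
    q = next(f.Q for f in fx if f.kind == "inlet")
    el_exact = -g_exact * length * q
    el_error = abs(el - el_exact) / el_exact

    q_out = next(f.Q for f in fx if f.kind == "outlet")
    mass_imbalance = abs(q - q_out) / abs(q)
    sim_div = _divergence_max(state, grid)
    return PoiseuilleReport(centerline_error, gradient_error, wss_error,
                            el_error, mass_imbalance, sim_div)


def _divergence_max(state, grid) -> float:
    d = (state.u[1:, :] - state.u[:-1, :]
         + state.v[:, 1:] - state.v[:, :-1]) / grid.h
    return float(np.max(np.abs(d[grid.fluid])))


@dataclass
class OscillatoryReport:
    alpha: float                  # Womersley number
    profile_l2_error: float       # worst relative L2 vs instantaneous parabola
    phases_checked: int


def oscillatory_channel_case(width: float = 0.002, u_mean: float = 0.1,
                             u_osc: float = 0.08, alpha: float = 0.4,
                             cells_across: int = 10,
                             props: FluidProperties | None = None,
                             n_check: int = 8) -> OscillatoryReport:
    """Low-Womersley oscillatory channel vs the quasi-steady parabola.

    The inlet mean speed is u_mean + u_osc sin(omega t) with omega chosen
    from the requested Womersley number.  After one settling period the
    interior profile is compared with the parabola of the instantaneous
    mean flow at ``n_check`` phases over one further period.
    """
    props = props or FluidProperties()
    a = width / 2
    omega = alpha**2 * props.nu / a**2
    period = 2 * np.pi / omega
    h = width / cells_across
    grid = build_channel(width, 10 * width, h, depth=width)

    fs = 512.0 / period
    t = np.arange(int(round(period * fs))) / fs
    wave = Waveform("IVC", t, u_mean + u_osc * np.sin(omega * t), "m/s")
    bc = BoundarySpec(inlets={"IVC": (wave, "parabolic")},
                      outlets={"RPA": 0.0})
    cfg = SolverConfig(n_cycles=2, discard_cycles=1)
    sim = Simulator(grid, bc, props, cfg)
    from .solver import _pick_dt

    dt = _pick_dt(grid, bc, props, cfg, period)
    check_times = period + np.linspace(0, period, n_check, endpoint=False)
    next_check = 0
    worst = 0.0
    mid = grid.nx // 2
    xi = (np.arange(grid.ny) + 0.5) / grid.ny
    shape = 6.0 * xi * (1 - xi)
    while sim.t < 2 * period - 1e-12 and next_check < n_check:
        sim.step(dt)
        if sim.t >= check_times[next_check] - dt / 2:
            u_profile = sim.u[mid, :]
            u_inst = u_mean + u_osc * np.sin(omega * sim.t)
            exact = shape * u_inst
            err = np.linalg.norm(u_profile - exact) / np.linalg.norm(exact)
            worst = max(worst, float(err))
            next_check += 1
    return OscillatoryReport(alpha, worst, next_check)
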