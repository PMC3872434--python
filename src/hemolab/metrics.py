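"""Hemodynamic evaluation metrics: energy loss, flow split, wall shear.

The junction is treated as a control volume with venous inlets and
pulmonary-artery outlets.  Per snapshot the module integrates port fluxes,
area-averaged static pressures and speeds, then forms

* the flow-distribution ratio  FR = Q_LPA / Q_inlet * 100%  (the share of
  total venous return sent to the left lung),
* the control-volume energy (power) loss
  EL(t) = sum_in (P + 1/2 rho <U^2>) Q  -  sum_out (P + 1/2 rho <U^2>) Q,
  optionally augmented with a port-inertance estimate of the unsteady
  velocity-potential term, and
* wall shear stress  tau_wall = mu dU_t/dn  at every solid-adjacent face
  (one-sided second-order difference; sign along the local tangent).

EL is gauge invariant: adding a constant to all pressures changes it by
that constant times the net mass imbalance, which the projection keeps at
machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import StaggeredGrid
from .solver import FlowState, FluidProperties, compute_reynolds

__all__ = [
    "PortFlux",
    "MetricsSeries",
    "WallShearField",
    "ELSeries",
    "port_fluxes",
    "compute_FR",
    "compute_EL",
    "compute_WSS",
    "normalize_pressure",
    "metrics_series",
    "grid_convergence_of_EL",
]


class MetricsError(ValueError):
    pass


@dataclass
class PortFlux:
    """Port integrals at one instant.

    ``Q`` is through-flow positive: into the domain at inlets, out of it at
    outlets, so mass balance reads sum_in Q - sum_out Q ~ 0.  ``P_mean`` is
    the area-averaged static pressure extrapolated to the port face plane;
    ``U_mean``/``U2_mean`` are the face-weighted mean speed and mean squared
    speed; ``ke_flux = 1/2 rho <U^2> Q``.
    """

    port: str
    kind: str
    Q: float
    P_mean: float
    U_mean: float
    U2_mean: float

    def ke_flux(self, rho: float) -> float:
        return 0.5 * rho * self.U2_mean * self.Q


def port_fluxes(state: FlowState, grid: StaggeredGrid,
                props: FluidProperties, copy_state: bool = True) -> list:
    """Integrate Q, P, U over every tagged port of a snapshot."""
    h, depth = grid.h, grid.depth
    out = []
    for name, p in grid.ports.items():
        which, fixed, span = grid.port_face_slices(name)
        if which == "u":
            un = state.u[fixed, span]
        else:
            un = state.v[span, fixed]
        # through-flow sign: inward for inlets, outward for outlets
        nsign = {"W": 1.0, "E": -1.0, "S": 1.0, "N": -1.0}[p.side]
        if p.kind == "outlet":
            nsign = -nsign
        q = float(np.sum(nsign * un) * h * depth)
        # pressure extrapolated from the two cells inward of the face
        P = state.p
        if p.side == "W":
            p1, p2 = P[0, span], P[1, span]
        elif p.side == "E":
            p1, p2 = P[-1, span], P[-2, span]
        elif p.side == "S":
            p1, p2 = P[span, 0], P[span, 1]
        else:
            p1, p2 = P[span, -1], P[span, -2]
        out.append(PortFlux(
            port=name,
            kind=p.kind,
            Q=q,
            P_mean=float(np.mean(1.5 * p1 - 0.5 * p2)),
            U_mean=float(np.mean(np.abs(un))),
            U2_mean=float(np.mean(un ** 2)),
        ))
    return out


def compute_FR(fluxes: list, outlet: str = "LPA") -> float:
    """Flow-distribution ratio: percent of total venous inflow sent to ``outlet``."""
    q_in = sum(f.Q for f in fluxes if f.kind == "inlet")
    if q_in <= 0:
        raise MetricsError("total inflow must be positive for FR")
    q_out = next(f.Q for f in fluxes if f.port == outlet)
    return 100.0 * q_out / q_in


@dataclass
class ELSeries:
    """Instantaneous, cumulative and time-averaged control-volume energy loss."""

    t: np.ndarray
    EL: np.ndarray                   # W, instantaneous
    cumulative_J: np.ndarray
    time_averaged_W: float
    estimator_gap_W: float = 0.0     # |<U^2> vs <U>^2 KE-estimator| difference
    unsteady_included: bool = False


def compute_EL(times, fluxes_t: list, props: FluidProperties,
               include_unsteady: bool = False,
               inertance_lengths: dict | None = None) -> ELSeries:
    """Control-volume power loss from a time series of port-flux lists.

    ``fluxes_t[k]`` is the ``port_fluxes`` list at ``times[k]``.  The total
    pressure flux uses the area-averaged squared speed; the alternative
    (area-averaged speed squared) is evaluated as a diagnostic and its
    time-averaged discrepancy reported.  With ``include_unsteady`` a port
    inertance term rho * L * d<U>/dt * Q approximates the unsteady
    velocity-potential contribution (L per port from
    ``inertance_lengths``); a global potential does not exist for viscous
    rotational flow, hence the default excludes it.
    """
    times = np.asarray(times, dtype=float)
    if len(fluxes_t) != times.size:
        raise MetricsError("times and flux series lengths differ")
    rho = props.rho
    el = np.zeros(times.size)
    el_alt = np.zeros(times.size)
    for k, fx in enumerate(fluxes_t):
        for f in fx:
            s = 1.0 if f.kind == "inlet" else -1.0
            el[k] += s * (f.P_mean + 0.5 * rho * f.U2_mean) * f.Q
            el_alt[k] += s * (f.P_mean + 0.5 * rho * f.U_mean ** 2) * f.Q
    if include_unsteady:
        ports = [f.port for f in fluxes_t[0]]
        for j, port in enumerate(ports):
            L = (inertance_lengths or {}).get(port, 0.0)
            if L == 0.0:
                continue
            U = np.array([fx[j].U_mean for fx in fluxes_t])
            Q = np.array([fx[j].Q for fx in fluxes_t])
            s = 1.0 if fluxes_t[0][j].kind == "inlet" else -1.0
            dUdt = np.gradient(U, times)
            el += s * rho * L * dUdt * Q
    from scipy.integrate import cumulative_trapezoid

    cum = np.concatenate([[0.0], cumulative_trapezoid(el, times)])
    span = times[-1] - times[0]
    avg = float(np.trapezoid(el, times) / span) if span > 0 else float(el[0])
    avg_alt = float(np.trapezoid(el_alt, times) / span) if span > 0 else float(el_alt[0])
    return ELSeries(times, el, cum, avg,
                    estimator_gap_W=abs(avg - avg_alt),
                    unsteady_included=include_unsteady)


@dataclass
class WallShearField:
    """Signed tangential viscous stress at solid-adjacent wall faces."""

    x: np.ndarray        # wall-face midpoint positions, m
    y: np.ndarray
    tau: np.ndarray      # Pa, along the +x (horizontal walls) or +y tangent
    orientation: np.ndarray  # "S","N","W","E": side of the fluid the wall is on

    @property
    def tau_max(self) -> float:
        return float(np.max(np.abs(self.tau))) if self.tau.size else 0.0


def compute_WSS(state: FlowState, grid: StaggeredGrid,
                props: FluidProperties, order: int = 2) -> WallShearField:
    """Wall shear stress tau = mu dU_t/dn from one-sided differences.

    For each fluid cell whose neighbour (or the domain boundary, away from
    ports) is solid, the wall-tangential velocity at h/2 and 3h/2 from the
    wall gives the order-2 one-sided gradient (9 u1 - u2) / (3 h); order=1
    uses 2 u1 / h (the solver's ghost-consistent form).
    """
    h = grid.h
    mu = props.mu
    nx, ny = grid.nx, grid.ny
    fluid = grid.fluid
    # cell-centered tangential velocities
    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :])   # x-velocity at centers
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:])
    solid = np.zeros((nx + 2, ny + 2), dtype=bool)
    solid[1:-1, 1:-1] = ~fluid
    solid[0, :] = solid[-1, :] = solid[:, 0] = solid[:, -1] = True
    # domain-boundary port faces are not walls
    for name, p in grid.ports.items():
        if p.side == "W":
            solid[0, 1 + p.lo:1 + p.hi] = False
        elif p.side == "E":
            solid[-1, 1 + p.lo:1 + p.hi] = False
        elif p.side == "S":
            solid[1 + p.lo:1 + p.hi, 0] = False
        else:
            solid[1 + p.lo:1 + p.hi, -1] = False

    xs, ys, taus, orients = [], [], [], []

    def emit(t1, t2, ori, xw, yw):
        if order == 2:
            tau = mu * (9.0 * t1 - t2) / (3.0 * h)
        else:
            tau = mu * 2.0 * t1 / h
        xs.extend(xw)
        ys.extend(yw)
        taus.extend(tau)
        orients.extend([ori] * len(xw))

    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    xc = (I + 0.5) * h
    yc = (J + 0.5) * h

    # wall above (solid at j+1): tangential = u, distances h/2 and 3h/2
    m = fluid & solid[1:-1, 2:]
    if m.any():
        t1 = uc[m]
        below_ok = np.zeros_like(m)
        below_ok[:, 1:] = fluid[:, :-1]
        t2 = np.where(below_ok[m], _shift_gather(uc, m, 0, -1), 3.0 * t1)
        # fallback keeps the order-1 value when no second sample exists
        emit(t1, t2, "N", xc[m], yc[m] + h / 2)
    # wall below
    m = fluid & solid[1:-1, :-2]
    if m.any():
        t1 = uc[m]
        above_ok = np.zeros_like(m)
        above_ok[:, :-1] = fluid[:, 1:]
        t2 = np.where(above_ok[m], _shift_gather(uc, m, 0, +1), 3.0 * t1)
        emit(t1, t2, "S", xc[m], yc[m] - h / 2)
    # wall right (solid at i+1): tangential = v
    m = fluid & solid[2:, 1:-1]
    if m.any():
        t1 = vc[m]
        left_ok = np.zeros_like(m)
        left_ok[1:, :] = fluid[:-1, :]
        t2 = np.where(left_ok[m], _shift_gather(vc, m, -1, 0), 3.0 * t1)
        emit(t1, t2, "E", xc[m] + h / 2, yc[m])
    # wall left
    m = fluid & solid[:-2, 1:-1]
    if m.any():
        t1 = vc[m]
        right_ok = np.zeros_like(m)
        right_ok[:-1, :] = fluid[1:, :]
        t2 = np.where(right_ok[m], _shift_gather(vc, m, +1, 0), 3.0 * t1)
        emit(t1, t2, "W", xc[m] - h / 2, yc[m])

    return WallShearField(np.asarray(xs), np.asarray(ys), np.asarray(taus),
                          np.asarray(orients))


def _shift_gather(field: np.ndarray, mask: np.ndarray, di: int, dj: int):
    """field[i+di, j+dj] for the True cells of mask (callers guarantee range)."""
    ii, jj = np.nonzero(mask)
    return field[np.clip(ii + di, 0, field.shape[0] - 1),
                 np.clip(jj + dj, 0, field.shape[1] - 1)]


def normalize_pressure(fluxes_t: list, reference_port: str = "LPA"):
    """Shift all port pressures so the reference port's minimum over time is 0.

    Returns ``(shifted_series, offset)``.  EL is invariant under the shift
    whenever inflow and outflow volume rates balance.
    """
    ref = [next(f for f in fx if f.port == reference_port) for fx in fluxes_t]
    offset = min(f.P_mean for f in ref)
    shifted = [
        [PortFlux(f.port, f.kind, f.Q, f.P_mean - offset, f.U_mean, f.U2_mean)
         for f in fx]
        for fx in fluxes_t
    ]
    return shifted, offset


@dataclass
class MetricsSeries:
    """Time-resolved summary metrics of one simulation run."""

    t: np.ndarray
    EL: np.ndarray
    FR_LPA: np.ndarray
    FR_RPA: np.ndarray
    Re: dict             # port -> array
    Cr: np.ndarray
    EL_time_averaged: float
    FR_time_averaged: float
    EL_series: ELSeries

    def to_frame(self) -> pd.DataFrame:
        data = {"t_s": self.t, "EL_W": self.EL,
                "FR_LPA_pct": self.FR_LPA, "FR_RPA_pct": self.FR_RPA,
                "Cr": self.Cr}
        for port, series in self.Re.items():
            data[f"Re_{port}"] = series
        return pd.DataFrame(data)


def metrics_series(result, char_lengths: dict,
                   include_unsteady: bool = False,
                   inertance_lengths: dict | None = None,
                   kept_only: bool = True) -> MetricsSeries:
    """Assemble EL/FR/Re/Cr time series from a solver RunResult.

    ``char_lengths`` maps port name to its characteristic (hydraulic)
    diameter for the Reynolds series.
    """
    keep = result.kept if kept_only else np.ones_like(result.times, bool)
    t = result.times[keep]
    ports = list(result.port_records)
    fluxes_t = []
    for k in np.nonzero(keep)[0]:
        fx = [PortFlux(port, result.grid.ports[port].kind,
                       result.port_records[port]["Q"][k],
                       result.port_records[port]["P"][k],
                       result.port_records[port]["U"][k],
                       result.port_records[port]["U2"][k])
              for port in ports]
        fluxes_t.append(fx)
    els = compute_EL(t, fluxes_t, result.props,
                     include_unsteady=include_unsteady,
                     inertance_lengths=inertance_lengths)
    q_in = np.sum([result.port_records[p]["Q"][keep] for p in ports
                   if result.grid.ports[p].kind == "inlet"], axis=0)
    fr_lpa = 100.0 * result.port_records["LPA"]["Q"][keep] / q_in \
        if "LPA" in ports else np.full(t.size, np.nan)
    fr_rpa = 100.0 * result.port_records["RPA"]["Q"][keep] / q_in \
        if "RPA" in ports else np.full(t.size, np.nan)
    re = {p: np.array([compute_reynolds(u, char_lengths[p], result.props)
                       for u in result.port_records[p]["U"][keep]])
          for p in ports if p in char_lengths}
    umax = np.max([result.port_records[p]["U"][keep] for p in ports], axis=0)
    cr = umax * result.dt / result.grid.h
    span = t[-1] - t[0] if t.size > 1 else 1.0
    fr_avg = float(np.trapezoid(fr_lpa, t) / span) if t.size > 1 else float(fr_lpa[0])
    return MetricsSeries(t, els.EL, fr_lpa, fr_rpa, re, cr,
                         els.time_averaged_W, fr_avg, els)


def grid_convergence_of_EL(geometry, make_bc, props: FluidProperties,
                           cells_across: list, steady_tol: float = 1e-4,
                           max_time: float = 8.0) -> pd.DataFrame:
    """Steady-state EL on successively finer rasterizations of the junction.

    ``cells_across`` lists the number of cells across the narrowest channel
    per level (e.g. [10, 14, 20]); ``make_bc(grid)`` builds the (steady)
    boundary spec for a given grid.  Returns a table of cell counts, EL and
    successive relative changes.
    """
    from .geometry import build_junction
    from .solver import run_steady

    if len(cells_across) < 3:
        raise MetricsError("need at least 3 refinement levels")
    w_min = min(geometry.widths.values())
    rows = []
    prev = None
    for m in cells_across:
        h = w_min / m
        grid = build_junction(geometry, h)
        bc = make_bc(grid)
        state = run_steady(grid, bc, props, steady_tol=steady_tol,
                           max_time=max_time)
        fx = port_fluxes(state, grid, props)
        el = compute_EL(np.array([state.t]), [fx], props).EL[0]
        change = np.nan if prev is None else abs(el - prev) / abs(prev)
        rows.append({"cells_across": m, "h_m": h, "n_fluid": grid.n_fluid,
                     "EL_W": el, "rel_change": change})
        prev = el
    return pd.DataFrame(rows)
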