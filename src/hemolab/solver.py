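"""Pulsatile laminar incompressible flow on the staggered junction grid.

Fractional-step (projection) solver for the incompressible Navier-Stokes
equations with constant density and viscosity (Newtonian blood, body forces
omitted), rigid no-slip walls, prescribed pulsatile velocity inlets and
prescribed-pressure outlets:

    rho du/dt + rho (u . grad) u = -grad p + mu lap u,   div u = 0.

Discretization: marker-and-cell (MAC) staggering (cell-centered pressure,
face-normal velocities), second-order upwind-biased advection with a
first-order fallback adjacent to boundaries, explicit second-order
Adams-Bashforth time advance of advection + diffusion, then a pressure
Poisson projection (sparse direct factorization, reused every step) that
renders each step's velocity field discretely divergence-free to machine
precision.  Outlet pressure enters the Poisson problem as a face Dirichlet
value; outlet velocity is zero-normal-gradient before projection.

The time step honours both the advective Courant bound Cr = u dt / h and
the explicit-diffusion bound dt <= h^2 rho / (4 mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import factorized

from .geometry import StaggeredGrid
from .waveforms import Waveform, sample_periodic

__all__ = [
    "FluidProperties",
    "BoundarySpec",
    "SolverConfig",
    "FlowState",
    "Simulator",
    "RunResult",
    "run",
    "run_steady",
    "select_timestep",
    "courant_number",
    "compute_reynolds",
    "check_laminar",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: density (kg/m^3) and dynamic viscosity (Pa s)."""

    rho: float = 1060.0
    mu: float = 0.004

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass
class BoundarySpec:
    """Per-port boundary conditions.

    ``inlets`` maps port name to ``(waveform_or_float, profile)`` with
    profile in {"flat", "parabolic"}; the waveform value is the
    instantaneous *mean* inflow speed across the port.  ``outlets`` maps
    port name to a pressure Waveform or a constant (Pa); 0.0 gives the
    zero-pressure outlet of the cardiac-only regime.
    """

    inlets: dict
    outlets: dict

    def inlet_value(self, port: str, t: float) -> float:
        src, _ = self.inlets[port]
        if isinstance(src, Waveform):
            return float(sample_periodic(src, t)[0])
        return float(src)

    def outlet_value(self, port: str, t: float) -> float:
        src = self.outlets[port]
        if isinstance(src, Waveform):
            return float(sample_periodic(src, t)[0])
        return float(src)

    def max_inlet_speed(self) -> float:
        out = 0.0
        for src, _ in self.inlets.values():
            if isinstance(src, Waveform):
                out = max(out, float(np.max(np.abs(src.v))))
            else:
                out = max(out, abs(float(src)))
        return out


@dataclass
class SolverConfig:
    """Run controls: Courant ceiling, cycles, warm-up discard, cadence."""

    cr_max: float = 0.3
    dt_fixed: float | None = None
    residual_tol: float = 1e-5
    n_cycles: int = 2
    discard_cycles: int = 1
    snapshots_per_cycle: int = 40
    velocity_headroom: float = 3.0  # interior-speed margin over the inlet peak

    def __post_init__(self) -> None:
        if not (0.0 < self.cr_max <= 1.0):
            raise ValueError("cr_max must lie in (0, 1]")
        if self.discard_cycles >= self.n_cycles and self.n_cycles > 0:
            raise ValueError("discard_cycles must be < n_cycles")


@dataclass
class FlowState:
    """Snapshot: face velocities u (nx+1, ny), v (nx, ny+1), pressure p, time."""

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    t: float


class _Orient:
    """Precomputed face masks / ghost signs for one momentum orientation."""

    def __init__(self, fluid: np.ndarray, gbot: np.ndarray, gtop: np.ndarray):
        nx, ny = fluid.shape
        left = np.zeros((nx + 1, ny), bool)
        left[1:, :] = fluid
        right = np.zeros((nx + 1, ny), bool)
        right[:-1, :] = fluid
        self.any = left | right          # face value is meaningful (maybe 0)
        self.int_ = left & right         # interior faces advanced by the solver
        self.gbot = gbot                 # tangential ghost sign at j = -1
        self.gtop = gtop                 # tangential ghost sign at j = ny
        self.keep = self.int_.copy()     # updated with port faces by Simulator


def _momentum_rhs(u: np.ndarray, vm: np.ndarray, O: _Orient, h: float,
                  nu: float) -> np.ndarray:
    """-(u.grad)u + nu lap u for one orientation on the full face array.

    ``u`` is the advanced component (nx+1, ny); ``vm`` the transverse
    component masked to zero on non-fluid faces (nx, ny+1).  Values are
    meaningful only on ``O.int_`` faces.
    """
    nx1, ny = u.shape

    # --- diffusion -------------------------------------------------------
    uN = np.empty_like(u)
    uN[:, :-1] = np.where(O.any[:, 1:], u[:, 1:], -u[:, :-1])
    uN[:, -1] = O.gtop * u[:, -1]
    uS = np.empty_like(u)
    uS[:, 1:] = np.where(O.any[:, :-1], u[:, :-1], -u[:, 1:])
    uS[:, 0] = O.gbot * u[:, 0]
    lap = uN + uS - 2.0 * u
    lap[1:-1, :] += u[2:, :] + u[:-2, :] - 2.0 * u[1:-1, :]
    lap /= h * h

    # --- streamwise advection d(uu)/dx ----------------------------------
    uc = 0.5 * (u[:-1, :] + u[1:, :])          # at cell centers
    f_pos = u[:-1, :].copy()                    # first-order fallback
    f_pos[1:, :] = np.where(O.any[:-2, :],
                            1.5 * u[1:-1, :] - 0.5 * u[:-2, :], u[1:-1, :])
    f_neg = u[1:, :].copy()
    f_neg[:-1, :] = np.where(O.any[2:, :],
                             1.5 * u[1:-1, :] - 0.5 * u[2:, :], u[1:-1, :])
    phi = uc * np.where(uc >= 0.0, f_pos, f_neg)
    adv = np.zeros_like(u)
    adv[1:-1, :] = (phi[1:, :] - phi[:-1, :]) / h

    # --- transverse advection d(vu)/dy at face corners ------------------
    vc = np.empty((nx1, ny + 1))
    vc[1:-1, :] = 0.5 * (vm[:-1, :] + vm[1:, :])
    vc[0, :] = vm[0, :]
    vc[-1, :] = vm[-1, :]
    below = np.empty((nx1, ny + 1))
    below[:, 1:] = u
    below[:, 0] = O.gbot * u[:, 0]
    above = np.empty((nx1, ny + 1))
    above[:, :-1] = u
    above[:, -1] = O.gtop * u[:, -1]
    g_pos = below.copy()
    g_pos[:, 2:] = np.where(O.any[:, :-1],
                            1.5 * u[:, 1:] - 0.5 * u[:, :-1], u[:, 1:])
    g_neg = above.copy()
    g_neg[:, :-2] = np.where(O.any[:, 1:],
                             1.5 * u[:, :-1] - 0.5 * u[:, 1:], u[:, :-1])
    G = vc * np.where(vc >= 0.0, g_pos, g_neg)
    adv += (G[:, 1:] - G[:, :-1]) / h

    return nu * lap - adv


def _parabolic_profile(m: int) -> np.ndarray:
    xi = (np.arange(m) + 0.5) / m
    prof = 6.0 * xi * (1.0 - xi)
    return prof / prof.mean()  # discrete mean exactly 1 -> exact port flux


class Simulator:
    """Stateful integrator bound to one (grid, boundary-spec, fluid) triple."""

    def __init__(self, grid: StaggeredGrid, bc: BoundarySpec,
                 props: FluidProperties, cfg: SolverConfig | None = None):
        self.grid = grid
        self.bc = bc
        self.props = props
        self.cfg = cfg or SolverConfig()
        nx, ny = grid.nx, grid.ny
        fluid = grid.fluid

        # tangential ghost signs: -1 (no slip / no tangential at inlets),
        # +1 (zero gradient) across outlet spans.
        gbot_u = -np.ones(nx + 1)
        gtop_u = -np.ones(nx + 1)
        gbot_vT = -np.ones(ny + 1)
        gtop_vT = -np.ones(ny + 1)
        for name, p in grid.ports.items():
            if p.kind != "outlet":
                continue
            if p.side == "S":
                gbot_u[p.lo:p.hi + 1] = 1.0
            elif p.side == "N":
                gtop_u[p.lo:p.hi + 1] = 1.0
            elif p.side == "W":
                gbot_vT[p.lo:p.hi + 1] = 1.0
            elif p.side == "E":
                gtop_vT[p.lo:p.hi + 1] = 1.0
        self.Ou = _Orient(fluid, gbot_u, gtop_u)
        self.Ov = _Orient(fluid.T, gbot_vT, gtop_vT)

        # port face bookkeeping on the u/v arrays
        self._inlet_faces = {}
        self._outlet_faces = {}
        for name, p in grid.ports.items():
            which, fixed, span = grid.port_face_slices(name)
            m = p.hi - p.lo
            if name in bc.inlets:
                _, shape = bc.inlets[name]
                prof = (_parabolic_profile(m) if shape == "parabolic"
                        else np.ones(m))
                # sign of the Cartesian component for *inflow*
                sign = {"W": 1.0, "E": -1.0, "S": 1.0, "N": -1.0}[p.side]
                self._inlet_faces[name] = (which, fixed, span, sign * prof)
                self._mark_keep(which, fixed, span)
            elif name in bc.outlets:
                self._outlet_faces[name] = (which, fixed, span, p.side)
                self._mark_keep(which, fixed, span)
            else:
                raise SolverError(f"port {name} has no boundary condition")

        self._build_poisson()
        self.u = np.zeros((nx + 1, ny))
        self.v = np.zeros((nx, ny + 1))
        self.p = np.zeros((nx, ny))
        self.t = 0.0
        self._Fu_old = None
        self._Fv_old = None
        self._dt_old = None
        self.max_divergence = 0.0
        self._apply_inlets(self.u, self.v, 0.0)

    # -- setup helpers ----------------------------------------------------

    def _mark_keep(self, which, fixed, span):
        if which == "u":
            self.Ou.keep[fixed, span] = True
        else:
            self.Ov.keep[fixed, span] = True  # transposed orientation: v.T

    def _build_poisson(self):
        g = self.grid
        nx, ny = g.nx, g.ny
        fluid = g.fluid
        idx = -np.ones((nx, ny), dtype=np.int64)
        nf = int(fluid.sum())
        idx[fluid] = np.arange(nf)
        rows, cols, vals = [], [], []
        mx = fluid[:-1, :] & fluid[1:, :]
        a = idx[:-1, :][mx]
        b = idx[1:, :][mx]
        rows.extend(np.concatenate([a, b, a, b]))
        cols.extend(np.concatenate([b, a, a, b]))
        vals.extend(np.concatenate([-np.ones(a.size), -np.ones(a.size),
                                    np.ones(a.size), np.ones(a.size)]))
        my = fluid[:, :-1] & fluid[:, 1:]
        a = idx[:, :-1][my]
        b = idx[:, 1:][my]
        rows.extend(np.concatenate([a, b, a, b]))
        cols.extend(np.concatenate([b, a, a, b]))
        vals.extend(np.concatenate([-np.ones(a.size), -np.ones(a.size),
                                    np.ones(a.size), np.ones(a.size)]))

        self._outlet_cells = {}
        for name, (which, fixed, span, side) in self._outlet_faces.items():
            if side == "W":
                cells = idx[0, span]
            elif side == "E":
                cells = idx[nx - 1, span]
            elif side == "S":
                cells = idx[span, 0]
            else:
                cells = idx[span, ny - 1]
            self._outlet_cells[name] = cells
            rows.extend(cells)
            cols.extend(cells)
            vals.extend(np.full(cells.size, 2.0))

        A = coo_matrix((np.asarray(vals), (np.asarray(rows), np.asarray(cols))),
                       shape=(nf, nf)).tocsc()
        self._poisson_solve = factorized(A)
        self._cell_idx = idx
        self._nf = nf

    # -- boundary application --------------------------------------------

    def _apply_inlets(self, u, v, t):
        for name, (which, fixed, span, prof) in self._inlet_faces.items():
            val = self.bc.inlet_value(name, t)
            if which == "u":
                u[fixed, span] = prof * val
            else:
                v[span, fixed] = prof * val

    def _extrapolate_outlets(self, u, v):
        for name, (which, fixed, span, side) in self._outlet_faces.items():
            if side == "W":
                u[0, span] = u[1, span]
            elif side == "E":
                u[-1, span] = u[-2, span]
            elif side == "S":
                v[span, 0] = v[span, 1]
            else:
                v[span, -1] = v[span, -2]

    def _divergence(self, u, v):
        return (u[1:, :] - u[:-1, :] + v[:, 1:] - v[:, :-1]) / self.grid.h

    # -- time stepping ----------------------------------------------------

    def step(self, dt: float) -> None:
        """Advance one time step (variable-step Adams-Bashforth + projection)."""
        g, props = self.grid, self.props
        h = g.h
        nu = props.nu
        u, v = self.u, self.v

        vm = v * self.Ov.keep.T  # zero non-meaningful faces for transverse terms
        um = u * self.Ou.keep
        Fu = _momentum_rhs(u, vm, self.Ou, h, nu)
        Fv = _momentum_rhs(v.T, um.T, self.Ov, h, nu).T

        if self._Fu_old is None:
            au, bu = 1.0, 0.0
        else:
            lam = dt / (2.0 * self._dt_old)
            au, bu = 1.0 + lam, -lam
        ustar = u.copy()
        vstar = v.copy()
        if bu == 0.0:
            ustar[self.Ou.int_] += dt * Fu[self.Ou.int_]
            vstar[self.Ov.int_.T] += dt * Fv[self.Ov.int_.T]
        else:
            ustar[self.Ou.int_] += dt * (au * Fu + bu * self._Fu_old)[self.Ou.int_]
            vstar[self.Ov.int_.T] += dt * (au * Fv + bu * self._Fv_old)[self.Ov.int_.T]

        t_new = self.t + dt
        self._apply_inlets(ustar, vstar, t_new)
        self._extrapolate_outlets(ustar, vstar)

        # pressure Poisson: Sum(p_C - p_nb) + 2 Sum_outlet (p_C - p_bc)
        #                   = -(h^2 rho / dt) div(u*)
        div = self._divergence(ustar, vstar)
        b = -(h * h * props.rho / dt) * div[g.fluid]
        for name, cells in self._outlet_cells.items():
            b[cells] += 2.0 * self.bc.outlet_value(name, t_new)
        pf = self._poisson_solve(b)
        P = np.zeros_like(self.p)
        P[g.fluid] = pf

        # velocity correction
        c = dt / props.rho
        gpx = (P[1:, :] - P[:-1, :]) / h
        ustar[1:-1, :][self.Ou.int_[1:-1, :]] -= c * gpx[self.Ou.int_[1:-1, :]]
        gpy = (P[:, 1:] - P[:, :-1]) / h
        vstar[:, 1:-1][self.Ov.int_.T[:, 1:-1]] -= c * gpy[self.Ov.int_.T[:, 1:-1]]
        for name, (which, fixed, span, side) in self._outlet_faces.items():
            pbc = self.bc.outlet_value(name, t_new)
            if side == "W":
                ustar[0, span] -= c * 2.0 * (P[0, span] - pbc) / h
            elif side == "E":
                ustar[-1, span] -= c * 2.0 * (pbc - P[-1, span]) / h
            elif side == "S":
                vstar[span, 0] -= c * 2.0 * (P[span, 0] - pbc) / h
            else:
                vstar[span, -1] -= c * 2.0 * (pbc - P[span, -1]) / h

        ustar *= self.Ou.keep
        vstar *= self.Ov.keep.T

        self.u, self.v, self.p, self.t = ustar, vstar, P, t_new
        self._Fu_old, self._Fv_old, self._dt_old = Fu, Fv, dt

    def state(self) -> FlowState:
        return FlowState(self.u.copy(), self.v.copy(), self.p.copy(), self.t)

    def max_speed(self) -> float:
        return max(float(np.max(np.abs(self.u))), float(np.max(np.abs(self.v))))

    def divergence_norm(self) -> float:
        d = self._divergence(self.u, self.v)
        return float(np.max(np.abs(d[self.grid.fluid])))


@dataclass
class RunResult:
    """Time-resolved port records plus sparse field snapshots."""

    times: np.ndarray
    port_records: dict          # port -> {"Q","P","U","U2"} arrays (see metrics)
    snapshots: list
    kept_from: float
    dt: float
    diagnostics: dict
    grid: StaggeredGrid
    props: FluidProperties
    bc: BoundarySpec

    @property
    def kept(self) -> np.ndarray:
        return self.times >= self.kept_from - 1e-12

    def snapshot_nearest(self, t: float) -> FlowState:
        k = int(np.argmin([abs(s.t - t) for s in self.snapshots]))
        return self.snapshots[k]


def _pick_dt(grid, bc, props, cfg, cycle_period) -> float:
    if cfg.dt_fixed is not None:
        dt = cfg.dt_fixed
    else:
        u_est = max(cfg.velocity_headroom * bc.max_inlet_speed(), 1e-6)
        dt_adv = cfg.cr_max * grid.h / u_est
        dt_diff = 0.8 * grid.h * grid.h / (4.0 * props.nu)
        dt = min(dt_adv, dt_diff)
    n = max(1, int(np.ceil(cycle_period / dt)))
    return cycle_period / n


def run(grid: StaggeredGrid, bc: BoundarySpec, props: FluidProperties,
        cfg: SolverConfig, cycle_period: float) -> RunResult:
    """Run ``cfg.n_cycles`` periods of length ``cycle_period``.

    The first ``cfg.discard_cycles`` periods are warm-up: they are
    integrated and recorded but flagged outside the kept analysis window.
    Port fluxes and area-averaged port pressures are recorded every step;
    full field snapshots at ``cfg.snapshots_per_cycle`` per period.
    """
    from . import metrics as _metrics

    sim = Simulator(grid, bc, props, cfg)
    dt = _pick_dt(grid, bc, props, cfg, cycle_period)
    T_total = cfg.n_cycles * cycle_period
    kept_from = cfg.discard_cycles * cycle_period

    times = []
    records = {name: {"Q": [], "P": [], "U": [], "U2": []}
               for name in grid.ports}
    snapshots = []
    snap_dt = cycle_period / cfg.snapshots_per_cycle
    next_snap = 0.0
    cr_seen = 0.0
    div_seen = 0.0
    halvings = 0

    while sim.t < T_total - 1e-12:
        sim.step(dt)
        umax = sim.max_speed()
        cr = umax * dt / grid.h
        cr_seen = max(cr_seen, cr)
        if not np.isfinite(umax):
            raise SolverError(
                f"solution diverged (NaN/Inf) at t={sim.t:.6g} s, dt={dt:g}"
            )
        if cr > 1.2 * cfg.cr_max:
            dt *= 0.5
            halvings += 1
            if halvings > 12:
                raise SolverError("time step collapsed; flow too fast for grid")
        div_seen = max(div_seen, sim.divergence_norm())
        times.append(sim.t)
        fx = _metrics.port_fluxes(sim.state(), grid, props, copy_state=False)
        for f in fx:
            rec = records[f.port]
            rec["Q"].append(f.Q)
            rec["P"].append(f.P_mean)
            rec["U"].append(f.U_mean)
            rec["U2"].append(f.U2_mean)
        if sim.t >= next_snap - dt / 2:
            snapshots.append(sim.state())
            next_snap += snap_dt

    times = np.asarray(times)
    records = {k: {kk: np.asarray(vv) for kk, vv in r.items()}
               for k, r in records.items()}
    diagnostics = {
        "cr_max_observed": cr_seen,
        "div_max": div_seen,
        "dt_halvings": halvings,
        "cycle_periodicity": _cycle_periodicity(times, records, cycle_period),
    }
    return RunResult(times, records, snapshots, kept_from, dt, diagnostics,
                     grid, props, bc)


def _cycle_periodicity(times, records, cycle_period) -> list:
    """Relative L2 change of port-flux waveforms between consecutive cycles."""
    n_cyc = int(np.floor((times[-1] + 1e-9) / cycle_period))
    if n_cyc < 2:
        return []
    tgrid = np.linspace(0, cycle_period, 200, endpoint=False)
    out = []
    for c in range(1, n_cyc):
        errs = []
        for rec in records.values():
            q0 = np.interp((c - 1) * cycle_period + tgrid, times, rec["Q"])
            q1 = np.interp(c * cycle_period + tgrid, times, rec["Q"])
            denom = np.linalg.norm(q1) + 1e-300
            errs.append(np.linalg.norm(q1 - q0) / denom)
        out.append(float(max(errs)))
    return out


def run_steady(grid: StaggeredGrid, bc: BoundarySpec, props: FluidProperties,
               cfg: SolverConfig | None = None, steady_tol: float = 1e-4,
               max_time: float = 20.0, check_every: int = 50) -> FlowState:
    """Integrate constant boundary conditions to steady state.

    Convergence: relative infinity-norm change of the velocity field over
    ``check_every`` steps below ``steady_tol``.
    """
    cfg = cfg or SolverConfig()
    sim = Simulator(grid, bc, props, cfg)
    dt = _pick_dt(grid, bc, props, cfg, max_time)
    u_prev = sim.u.copy()
    v_prev = sim.v.copy()
    k = 0
    halvings = 0
    while sim.t < max_time:
        sim.step(dt)
        k += 1
        umax = sim.max_speed()
        if not np.isfinite(umax):
            raise SolverError(f"diverged at t={sim.t:.6g}")
        if umax * dt / grid.h > 1.2 * cfg.cr_max:
            dt *= 0.5
            halvings += 1
            if halvings > 12:
                raise SolverError("time step collapsed in steady run")
        if k % check_every == 0:
            scale = max(sim.max_speed(), 1e-12)
            change = max(np.max(np.abs(sim.u - u_prev)),
                         np.max(np.abs(sim.v - v_prev))) / scale
            if change < steady_tol:
                return sim.state()
            u_prev = sim.u.copy()
            v_prev = sim.v.copy()
    return sim.state()


# ---------------------------------------------------------------------------
# Small dimensionless-number utilities
# ---------------------------------------------------------------------------

def courant_number(u_mean: float, dt: float, dI: float) -> float:
    """Cr = u dt / dI (advective stability/accuracy ratio)."""
    return u_mean * dt / dI


def select_timestep(state: FlowState, grid: StaggeredGrid, cr_max: float,
                    props: FluidProperties | None = None,
                    dt_fixed: float = 1e-4) -> float:
    """Time step from the Courant bound using the current mean face speed.

    Returns ``cr_max * h / u_mean``; with ``props`` given the explicit
    diffusive bound ``h^2 rho / (4 mu)`` caps the result.  An all-zero field
    returns ``dt_fixed``.
    """
    if not (np.all(np.isfinite(state.u)) and np.all(np.isfinite(state.v))):
        raise SolverError("velocity field contains non-finite values")
    O = _Orient(grid.fluid, -np.ones(grid.nx + 1), -np.ones(grid.nx + 1))
    Ov = _Orient(grid.fluid.T, -np.ones(grid.ny + 1), -np.ones(grid.ny + 1))
    speeds = np.concatenate([np.abs(state.u[O.any]), np.abs(state.v[Ov.any.T])])
    u_mean = float(speeds.mean()) if speeds.size else 0.0
    if u_mean <= 0.0:
        return dt_fixed
    dt = cr_max * grid.h / u_mean
    if props is not None:
        dt = min(dt, grid.h * grid.h * props.rho / (4.0 * props.mu))
    return dt


def compute_reynolds(U: float, D: float, props: FluidProperties) -> float:
    """Re = rho U D / mu."""
    if U < 0 or D <= 0:
        raise ValueError("need U >= 0 and D > 0")
    return props.rho * U * D / props.mu


@dataclass
class LaminarReport:
    threshold: float
    flags: list          # (port, time, Re) above threshold
    re_max: float

    @property
    def laminar(self) -> bool:
        return not self.flags


def check_laminar(metrics, threshold: float = 1000.0) -> LaminarReport:
    """Flag instants whose port Reynolds number exceeds ``threshold``.

    Informational only (the laminar model is retained regardless).
    ``metrics`` is a MetricsSeries (or anything with ``t`` and ``Re``:
    a dict port -> array).
    """
    flags = []
    re_max = 0.0
    for port, series in metrics.Re.items():
        series = np.asarray(series)
        if series.size:
            re_max = max(re_max, float(np.max(series)))
        for k in np.nonzero(series > threshold)[0]:
            flags.append((port, float(metrics.t[k]), float(series[k])))
    return LaminarReport(threshold, flags, re_max)
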