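"""Idealized planar cavopulmonary junction on a staggered Cartesian grid.

The patient vessel is replaced by a parameterized planar cross: the IVC
enters from below, the SVC from above (its centerline laterally offset from
the IVC's), and the LPA/RPA arms leave to the left and right.  A nominal
out-of-plane depth converts planar face fluxes into volumetric flow.  The
mask is rasterized onto a uniform marker-and-cell (MAC) grid: cell-centered
pressure, face-centered velocities, ports tagged on the domain boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "JunctionGeometry",
    "Port",
    "StaggeredGrid",
    "build_junction",
    "build_channel",
    "refine",
    "characteristic_length",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class JunctionGeometry:
    """Channel widths / offsets of the idealized junction, SI units (m).

    ``arm_length`` is the straight extension of every port channel from the
    central junction block out to its boundary port; it must be at least
    three channel widths so inflow/outflow regions can develop.  ``depth``
    is the out-of-plane reference depth used to convert planar flux to
    volumetric flow.
    """

    d_ivc: float = 0.009
    d_svc: float = 0.009
    d_lpa: float = 0.009
    d_rpa: float = 0.009
    caval_offset: float = 0.009
    arm_length: float = 0.027
    depth: float = 0.009

    def __post_init__(self) -> None:
        widths = (self.d_ivc, self.d_svc, self.d_lpa, self.d_rpa)
        if min(widths) <= 0 or self.arm_length <= 0 or self.depth <= 0:
            raise GeometryError("all widths, arm_length and depth must be > 0")
        if self.caval_offset < 0:
            raise GeometryError("caval_offset must be >= 0")
        if self.arm_length < 3 * max(widths) - 1e-12:
            raise GeometryError(
                "arm_length must be >= 3x the largest channel width "
                "(fully developed inflow/outflow region)"
            )
        if self.caval_offset > 3 * max(widths) + 1e-12:
            raise GeometryError(
                "caval_offset too large: caval channels no longer meet over "
                "a common junction block (limit 3x the largest width)"
            )

    @property
    def widths(self) -> dict:
        return {"IVC": self.d_ivc, "SVC": self.d_svc,
                "LPA": self.d_lpa, "RPA": self.d_rpa}


@dataclass(frozen=True)
class Port:
    """A contiguous run of boundary faces on one side of the domain.

    ``side`` is one of W/E/S/N; ``lo``/``hi`` are the cell-index span along
    that side (hi exclusive), so the port owns faces lo..hi-1.
    """

    name: str
    side: str
    kind: str  # "inlet" | "outlet"
    lo: int
    hi: int

    @property
    def n_faces(self) -> int:
        return self.hi - self.lo

    @property
    def outward_normal(self) -> tuple[int, int]:
        return {"W": (-1, 0), "E": (1, 0), "S": (0, -1), "N": (0, 1)}[self.side]


@dataclass
class StaggeredGrid:
    """Uniform MAC grid: ``fluid[i, j]`` cell mask, ports on the boundary."""

    h: float
    fluid: np.ndarray  # bool, shape (nx, ny); index [i, j], i along x
    ports: dict
    depth: float

    @property
    def nx(self) -> int:
        return self.fluid.shape[0]

    @property
    def ny(self) -> int:
        return self.fluid.shape[1]

    @property
    def n_fluid(self) -> int:
        return int(self.fluid.sum())

    @property
    def fluid_area(self) -> float:
        return self.n_fluid * self.h * self.h

    def port_face_slices(self, name: str):
        """(array, index) addressing of a port's normal-velocity faces.

        Returns ``(which, fixed_index, span_slice)`` where ``which`` is "u"
        for W/E ports and "v" for S/N ports; e.g. a W port's faces are
        ``u[0, lo:hi]``.
        """
        p = self.ports[name]
        if p.side == "W":
            return "u", 0, slice(p.lo, p.hi)
        if p.side == "E":
            return "u", self.nx, slice(p.lo, p.hi)
        if p.side == "S":
            return "v", 0, slice(p.lo, p.hi)
        if p.side == "N":
            return "v", self.ny, slice(p.lo, p.hi)
        raise GeometryError(f"bad side {p.side!r}")

    def validate(self) -> None:
        from scipy import ndimage

        lab, n = ndimage.label(self.fluid, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        if n != 1:
            raise GeometryError(f"fluid region is not 4-connected ({n} components)")
        for name, p in self.ports.items():
            cells = self._port_cells(p)
            if not self.fluid[cells].all():
                raise GeometryError(f"port {name} not fully backed by fluid cells")

    def _port_cells(self, p: Port):
        if p.side == "W":
            return (0, slice(p.lo, p.hi))
        if p.side == "E":
            return (self.nx - 1, slice(p.lo, p.hi))
        if p.side == "S":
            return (slice(p.lo, p.hi), 0)
        return (slice(p.lo, p.hi), self.ny - 1)


def _to_index(x: float, h: float) -> int:
    i = int(round(x / h))
    return i


def build_junction(g: JunctionGeometry, h: float) -> StaggeredGrid:
    """Rasterize the junction onto a uniform grid of cell size ``h``.

    Requires at least 10 cells across every channel.  Rectangle edges are
    snapped to the nearest grid line, so widths that are integer multiples
    of ``h`` rasterize exactly.
    """
    widths = g.widths
    if h > min(widths.values()) / 10 + 1e-12:
        raise GeometryError(
            f"h={h:g} m too coarse: need h <= min(width)/10 = "
            f"{min(widths.values())/10:g} m (>= 10 cells across every channel)"
        )
    d_pa = max(g.d_lpa, g.d_rpa)
    # junction block vertical extent
    yj0 = g.arm_length
    yj1 = yj0 + d_pa
    y_c = 0.5 * (yj0 + yj1)
    Ly = yj1 + g.arm_length
    # caval channels: IVC left edge defines the junction block's left edge
    x_iv0 = g.arm_length
    x_iv1 = x_iv0 + g.d_ivc
    x_sv0 = x_iv0 + g.caval_offset
    x_sv1 = x_sv0 + g.d_svc
    xj0 = min(x_iv0, x_sv0)
    xj1 = max(x_iv1, x_sv1)
    Lx = xj1 + g.arm_length

    nx, ny = _to_index(Lx, h), _to_index(Ly, h)
    fluid = np.zeros((nx, ny), dtype=bool)

    def rect(x0, x1, y0, y1):
        fluid[_to_index(x0, h):_to_index(x1, h),
              _to_index(y0, h):_to_index(y1, h)] = True

    rect(0.0, xj0, y_c - g.d_lpa / 2, y_c + g.d_lpa / 2)        # LPA arm
    rect(xj1, Lx, y_c - g.d_rpa / 2, y_c + g.d_rpa / 2)         # RPA arm
    rect(xj0, xj1, yj0, yj1)                                     # junction block
    rect(x_iv0, x_iv1, 0.0, yj1)                                 # IVC channel
    rect(x_sv0, x_sv1, yj0, Ly)                                  # SVC channel

    ports = {
        "IVC": Port("IVC", "S", "inlet", _to_index(x_iv0, h), _to_index(x_iv1, h)),
        "SVC": Port("SVC", "N", "inlet", _to_index(x_sv0, h), _to_index(x_sv1, h)),
        "LPA": Port("LPA", "W", "outlet",
                    _to_index(y_c - g.d_lpa / 2, h), _to_index(y_c + g.d_lpa / 2, h)),
        "RPA": Port("RPA", "E", "outlet",
                    _to_index(y_c - g.d_rpa / 2, h), _to_index(y_c + g.d_rpa / 2, h)),
    }
    grid = StaggeredGrid(h=h, fluid=fluid, ports=ports, depth=g.depth)
    grid.validate()
    return grid


def build_channel(width: float, length: float, h: float, depth: float,
                  inlet: str = "IVC", outlet: str = "RPA") -> StaggeredGrid:
    """Straight horizontal channel (W inlet, E outlet) for solver benchmarks."""
    if h > width / 2:
        raise GeometryError("h too coarse for channel")
    nx, ny = _to_index(length, h), _to_index(width, h)
    if nx < 2 or ny < 2:
        raise GeometryError("channel must be at least 2 cells in each direction")
    fluid = np.ones((nx, ny), dtype=bool)
    ports = {
        inlet: Port(inlet, "W", "inlet", 0, ny),
        outlet: Port(outlet, "E", "outlet", 0, ny),
    }
    grid = StaggeredGrid(h=h, fluid=fluid, ports=ports, depth=depth)
    grid.validate()
    return grid


def refine(grid: StaggeredGrid, factor: int) -> StaggeredGrid:
    """Split every cell ``factor`` times per axis; ports keep their spans."""
    if int(factor) != factor or factor < 2:
        raise GeometryError("refinement factor must be an integer >= 2")
    factor = int(factor)
    fluid = np.repeat(np.repeat(grid.fluid, factor, axis=0), factor, axis=1)
    ports = {
        name: replace(p, lo=p.lo * factor, hi=p.hi * factor)
        for name, p in grid.ports.items()
    }
    return StaggeredGrid(h=grid.h / factor, fluid=fluid, ports=ports,
                         depth=grid.depth)


def characteristic_length(g: JunctionGeometry, port: str) -> float:
    """Hydraulic diameter of a port channel: 2*w*d/(w+d) for a w x d section."""
    widths = g.widths
    if port not in widths:
        raise GeometryError(f"unknown port {port!r}")
    w = widths[port]
    return 2.0 * w * g.depth / (w + g.depth)
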