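"""Legacy ASCII VTK structured-points export of masks and flow snapshots.

The uniform Cartesian layout maps directly onto VTK STRUCTURED_POINTS with
cell data; files open in ParaView/VisIt for inspection.  Velocities are
interpolated from faces to cell centers; the out-of-plane component is 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .geometry import StaggeredGrid
from .solver import FlowState

__all__ = ["write_mask_vtk", "write_snapshot_vtk"]


def _header(fh, title: str, grid: StaggeredGrid) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
    fh.write(f"DIMENSIONS {grid.nx + 1} {grid.ny + 1} 1\n")
    fh.write("ORIGIN 0 0 0\n")
    fh.write(f"SPACING {grid.h:.9g} {grid.h:.9g} {grid.h:.9g}\n")
    fh.write(f"CELL_DATA {grid.nx * grid.ny}\n")


def _scalar(fh, name: str, field: np.ndarray) -> None:
    fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
    # VTK cell ordering: x fastest -> field[i, j] written j-major
    np.savetxt(fh, field.T.reshape(-1, 1), fmt="%.7g")


def write_mask_vtk(path, grid: StaggeredGrid) -> None:
    with open(Path(path), "w") as fh:
        _header(fh, "junction fluid mask", grid)
        _scalar(fh, "fluid", grid.fluid.astype(float))


def write_snapshot_vtk(path, state: FlowState, grid: StaggeredGrid,
                       extra: dict | None = None) -> None:
    """Write pressure, cell-centered velocity and mask for one snapshot."""
    uc = 0.5 * (state.u[:-1, :] + state.u[1:, :]) * grid.fluid
    vc = 0.5 * (state.v[:, :-1] + state.v[:, 1:]) * grid.fluid
    with open(Path(path), "w") as fh:
        _header(fh, f"flow snapshot t={state.t:.6g} s", grid)
        _scalar(fh, "pressure_Pa", state.p * grid.fluid)
        _scalar(fh, "fluid", grid.fluid.astype(float))
        fh.write("VECTORS velocity_m_s float\n")
        flat = np.zeros((grid.nx * grid.ny, 3))
        flat[:, 0] = uc.T.reshape(-1)
        flat[:, 1] = vc.T.reshape(-1)
        np.savetxt(fh, flat, fmt="%.7g")
        for name, field in (extra or {}).items():
            _scalar(fh, name, field)
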