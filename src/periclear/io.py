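"""Text-based export of grids, fields and time series.

Everything written here is plain text: legacy-ASCII VTK structured-points
files for visualization, CSV for time series and summaries, and a JSON
manifest capturing the full provenance of a run.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd

from .geometry import GeometryGrid

if TYPE_CHECKING:  # pragma: no cover
    from .solver import SimulationResult

__all__ = ["write_vtk", "write_distance_csv", "write_mass_csv",
           "write_manifest", "result_frame", "save_geometry", "load_geometry"]


def write_vtk(path: str | Path, grid: GeometryGrid,
              fields: Mapping[str, np.ndarray]) -> Path:
    """Write cell-centred scalar fields as a legacy-ASCII VTK file.

    The grid is emitted as STRUCTURED_POINTS with point data at cell
    centres, which every VTK-reading tool (ParaView, pyvista, VisIt)
    accepts. Arrays must be shaped ``(nx, ny)``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("periclear concentration fields\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {grid.nx} {grid.ny} 1\n")
        fh.write(f"ORIGIN {grid.origin[0]:.9g} {grid.origin[1]:.9g} 0\n")
        fh.write(f"SPACING {grid.dx:.9g} {grid.dx:.9g} {grid.dx:.9g}\n")
        fh.write(f"POINT_DATA {grid.nx * grid.ny}\n")
        for name, arr in fields.items():
            if arr.shape != (grid.nx, grid.ny):
                raise ValueError(f"field {name!r} has shape {arr.shape}, "
                                 f"expected {(grid.nx, grid.ny)}")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest: transpose to (ny, nx) then ravel
            np.savetxt(fh, arr.T.reshape(grid.ny, grid.nx), fmt="%.9e")
    return path


def result_frame(result: "SimulationResult") -> pd.DataFrame:
    """Distance and mass series of a run as one tidy DataFrame."""
    return pd.DataFrame({
        "time_s": result.times,
        "dist_ecs_m": result.dist_ecs,
        "dist_membrane_m": result.dist_membrane,
        "dist_combined_m": result.dist_combined,
        "moles_ecs": result.moles_ecs,
        "moles_membrane": result.moles_membrane,
        "injected_net_mol": result.injected_net,
    })


def write_distance_csv(path: str | Path, result: "SimulationResult") -> Path:
    path = Path(path)
    cols = ["time_s", "dist_ecs_m", "dist_membrane_m", "dist_combined_m"]
    result_frame(result)[cols].to_csv(path, index=False, float_format="%.9g")
    return path


def write_mass_csv(path: str | Path, result: "SimulationResult") -> Path:
    path = Path(path)
    cols = ["time_s", "moles_ecs", "moles_membrane", "injected_net_mol"]
    result_frame(result)[cols].to_csv(path, index=False, float_format="%.12g")
    return path


def write_manifest(path: str | Path, payload: Mapping) -> Path:
    """JSON manifest with deterministic key order."""
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def save_geometry(path: str | Path, grid: GeometryGrid) -> Path:
    """Persist a rasterized grid as a text label matrix + JSON sidecar.

    ``<path>`` holds the region labels (one grid row per line, x fastest);
    ``<path>.meta.json`` holds spacing, origin, fibre axes and needle data.
    """
    path = Path(path)
    np.savetxt(path, grid.labels.T, fmt="%d")
    meta = {
        "dx": grid.dx, "nx": grid.nx, "ny": grid.ny,
        "origin": list(grid.origin),
        "white_id": grid.white_id.T.tolist() if grid.fiber_axes else None,
        "fiber_axes": [list(a) for a in grid.fiber_axes],
        "needle_tip": list(grid.needle_tip) if grid.needle_tip else None,
        "inflow_i": grid.inflow[0].tolist(),
        "inflow_j": grid.inflow[1].tolist(),
        "drainage_direction": list(grid.drainage_direction),
        "checksum": grid.checksum(),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2) + "\n")
    return path


def load_geometry(path: str | Path) -> GeometryGrid:
    """Inverse of :func:`save_geometry`; verifies the stored checksum."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    labels = np.loadtxt(path, dtype=np.uint8).reshape(meta["ny"], meta["nx"]).T
    if meta["white_id"] is not None:
        white_id = np.asarray(meta["white_id"], dtype=np.int16).T
    else:
        white_id = np.full((meta["nx"], meta["ny"]), -1, dtype=np.int16)
    grid = GeometryGrid(
        dx=meta["dx"], nx=meta["nx"], ny=meta["ny"],
        origin=tuple(meta["origin"]), labels=labels, white_id=white_id,
        fiber_axes=tuple(tuple(a) for a in meta["fiber_axes"]),
        needle_tip=tuple(meta["needle_tip"]) if meta["needle_tip"] else None,
        inflow=(np.asarray(meta["inflow_i"], dtype=np.intp),
                np.asarray(meta["inflow_j"], dtype=np.intp)),
        drainage_direction=tuple(meta["drainage_direction"]),
    )
    if grid.checksum() != meta["checksum"]:
        raise ValueError(f"geometry file {path} failed its checksum")
    return grid
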