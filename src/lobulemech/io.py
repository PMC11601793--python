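"""Raster and result I/O: CSV, legacy-ASCII VTK, JSON.

Rasters are written as tidy CSV (i, j, x_mm, y_mm, value) and as legacy
VTK ``STRUCTURED_POINTS`` image data for quick inspection in ParaView.
The VTK writer covers exactly the scalar-field-on-a-uniform-grid case
this package needs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import UnitCellGeometry

__all__ = ["raster_to_csv", "raster_to_vtk", "result_to_json"]


def raster_to_csv(
    grid: np.ndarray, cell: UnitCellGeometry, path, value_name: str = "value"
) -> pd.DataFrame:
    """Write a (ny, nx) raster as tidy CSV at pixel-center coordinates."""
    ny, nx = grid.shape
    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    df = pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "x_mm": (ii.ravel() + 0.5) * cell.width / nx,
            "y_mm": (jj.ravel() + 0.5) * cell.height / ny,
            value_name: np.asarray(grid).ravel(),
        }
    )
    df.to_csv(path, index=False)
    return df


def raster_to_vtk(
    fields: dict[str, np.ndarray], cell: UnitCellGeometry, path
) -> None:
    """Write scalar rasters as one legacy-ASCII VTK STRUCTURED_POINTS file.

    All fields must share a (ny, nx) shape; complex fields are split
    into _real/_imag pairs.
    """
    shapes = {f.shape for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one raster shape")
    ny, nx = shapes.pop()
    flat: dict[str, np.ndarray] = {}
    for name, arr in fields.items():
        a = np.asarray(arr)
        if np.iscomplexobj(a):
            flat[name + "_real"] = a.real
            flat[name + "_imag"] = a.imag
        else:
            flat[name] = a.astype(float)
    lines = [
        "# vtk DataFile Version 3.0",
        "lobulemech raster",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {0.5 * cell.width / nx} {0.5 * cell.height / ny} 0",
        f"SPACING {cell.width / nx} {cell.height / ny} 1",
        f"POINT_DATA {nx * ny}",
    ]
    for name, a in flat.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.10g}" for v in row) for row in a)
    Path(path).write_text("\n".join(lines) + "\n")


def result_to_json(result, path=None) -> str:
    """Serialize a HomogenizationResult (moduli in Pa) to JSON."""
    obj = {
        "Gp_Pa": result.G_eff.storage,
        "Gpp_Pa": result.G_eff.loss,
        "tau_s": result.tau_eff,
        "frequency_Hz": result.frequency,
        "E_column_Pa": {
            "real": [float(v) for v in result.E_column.real],
            "imag": [float(v) for v in result.E_column.imag],
        },
        "metadata": result.metadata,
    }
    s = json.dumps(obj, indent=2)
    if path is not None:
        Path(path).write_text(s)
    return s
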