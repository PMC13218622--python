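"""Output writers: legacy-ASCII VTK structured grids, CSV series, HDF5 checkpoints."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = ["write_vtk", "write_series_csv", "write_summary_json",
           "save_checkpoint", "load_checkpoint"]


def write_vtk(path, grid: Grid, cell_fields: dict, title: str = "shearclot"):
    """Write cell-centered fields as a legacy ASCII VTK structured-points file."""
    path = Path(path)
    dims = grid.dims + (1,) * (3 - grid.ndim)
    spacing = grid.spacing + (grid.depth_mm,) * (3 - grid.ndim)
    origin = grid.origin + (0.0,) * (3 - grid.ndim)
    ncell = int(np.prod(dims))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {dims[0] + 1} {dims[1] + 1} {dims[2] + 1}\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} {origin[2]}\n")
        fh.write(f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}\n")
        fh.write(f"CELL_DATA {ncell}\n")
        for name, arr in cell_fields.items():
            a = np.asarray(arr, dtype=float).reshape(grid.dims)
            flat = a.reshape(dims, order="C").ravel(order="F")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, flat, fmt="%.8g")
    return path


def write_series_csv(path, series_dict: dict):
    df = pd.DataFrame(series_dict)
    df.to_csv(path, index=False)
    return Path(path)


def write_summary_json(path, summary: dict):
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    return Path(path)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def save_checkpoint(path, grid: Grid, field_dict: dict, t: float):
    """All fields in an HDF5 container for restart."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["t"] = t
        f.attrs["dims"] = grid.dims
        f.attrs["spacing"] = grid.spacing
        for name, arr in field_dict.items():
            f.create_dataset(name, data=np.asarray(arr))
    return Path(path)


def load_checkpoint(path):
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        t = float(f.attrs["t"])
        for name in f.keys():
            out[name] = f[name][...]
    return t, out
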