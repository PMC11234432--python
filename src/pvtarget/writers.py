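"""Shared plain-text writers: gridded CSV and legacy-VTK structured points."""

from __future__ import annotations

import numpy as np


def write_grid_csv(path, array2d, spacing: float, origin: tuple,
                   name: str = "value"):
    """Write a cell-centered 2D scalar grid with a small header."""
    arr = np.asarray(array2d)
    with open(path, "w") as fh:
        fh.write(f"# name {name}\n")
        fh.write(f"# spacing_m {spacing!r}\n")
        fh.write(f"# origin_m {origin[0]!r} {origin[1]!r}\n")
        fh.write(f"# shape {arr.shape[0]} {arr.shape[1]} (x-index rows)\n")
        np.savetxt(fh, arr.T[::-1], fmt="%.8g", delimiter=",")


def write_vtk_structured(path, fields: dict, spacing: float, origin: tuple):
    """Legacy-VTK STRUCTURED_POINTS file with named cell scalars.

    ``fields`` maps names to 2D arrays (x-index first); NaNs are written
    as-is (viewers blank them).
    """
    first = next(iter(fields.values()))
    nx, ny = np.asarray(first).shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\npvtarget field export\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {origin[0]} {origin[1]} 0\n")
        fh.write(f"SPACING {spacing} {spacing} 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, arr in fields.items():
            a = np.asarray(arr, dtype=float)
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest
            np.savetxt(fh, a.T.reshape(-1, 1), fmt="%.6g")
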