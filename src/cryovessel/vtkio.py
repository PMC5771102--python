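"""Minimal legacy-VTK (ASCII structured points) writer for visual inspection.

Writes cell data on the uniform voxel grid in a form ParaView/VisIt open
directly.  Only the legacy ASCII format is emitted, keeping the package
dependency-free for export.
"""

from __future__ import annotations

import numpy as np


def write_structured_points(path, grid, cell_data: dict[str, np.ndarray]) -> None:
    """Write ``cell_data`` arrays (shape == grid.shape, or shape + (3,) for
    vectors) as legacy VTK STRUCTURED_POINTS cell data.  Lengths in mm."""
    nx, ny, nz = grid.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncryovessel field\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        f.write(f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}\n")
        f.write(f"SPACING {grid.h} {grid.h} {grid.h}\n")
        f.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in cell_data.items():
            arr = np.asarray(arr)
            if arr.shape == (nx, ny, nz):
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "float"
                f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                flat = arr.transpose(2, 1, 0).ravel()  # VTK is x-fastest
                np.savetxt(f, flat.reshape(-1, 1), fmt="%d" if kind == "int" else "%.6g")
            elif arr.shape == (nx, ny, nz, 3):
                f.write(f"VECTORS {name} float\n")
                flat = arr.transpose(2, 1, 0, 3).reshape(-1, 3)
                np.savetxt(f, flat, fmt="%.6g")
            else:
                raise ValueError(f"bad shape {arr.shape} for field {name}")
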