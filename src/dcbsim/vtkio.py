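"""Plain-text output: legacy-VTK snapshots and CSV field/ledger files.

Fields live on a rectilinear (r, z) grid, which maps directly onto the
legacy ASCII ``RECTILINEAR_GRID`` dataset (cell data; the grid is one cell
deep in the third direction).  Field CSV files carry one row per cell with
indices, centre coordinates, region label and concentration, and can be
read back against the mesh that produced them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mesh import REGION_NAMES, AxiMesh
from .transport import ConcentrationField

__all__ = ["write_vtk", "write_field_csv", "read_field_csv"]


def write_vtk(mesh: AxiMesh, path, cell_data: dict | None = None, title="dcbsim field"):
    """Write the mesh (and optional per-cell scalars) as legacy ASCII VTK.

    ``cell_data`` maps scalar names to full-grid ``(nr, nz)`` arrays.  The
    region label is always included.  VTK orders cell data with the first
    coordinate varying fastest, which matches Fortran-order raveling of the
    ``(nr, nz)`` arrays.
    """
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.labels.astype(float))
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {mesh.nr + 1} {mesh.nz + 1} 1",
        f"X_COORDINATES {mesh.nr + 1} double",
        " ".join(f"{v:.9e}" for v in mesh.r_edges),
        f"Y_COORDINATES {mesh.nz + 1} double",
        " ".join(f"{v:.9e}" for v in mesh.z_edges),
        "Z_COORDINATES 1 double",
        "0.0",
        f"CELL_DATA {mesh.n_cells}",
    ]
    for name, arr in cell_data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (mesh.nr, mesh.nz):
            raise ValidationError(f"cell data {name!r} has shape {arr.shape}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        flat = arr.ravel(order="F")
        lines.extend(
            " ".join(f"{v:.9e}" for v in flat[k : k + 6]) for k in range(0, len(flat), 6)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_csv(field: ConcentrationField, path):
    mesh = field.mesh
    ii, jj = np.meshgrid(np.arange(mesh.nr), np.arange(mesh.nz), indexing="ij")
    frame = pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "r_m": mesh.r_centers[ii.ravel()],
            "z_m": mesh.z_centers[jj.ravel()],
            "region": [REGION_NAMES[c] for c in mesh.labels.ravel()],
            "phi_kg_per_m3": field.values.ravel(),
        }
    )
    frame.to_csv(path, index=False)


def read_field_csv(path, mesh: AxiMesh) -> ConcentrationField:
    frame = pd.read_csv(path)
    required = {"i", "j", "phi_kg_per_m3"}
    if not required <= set(frame.columns):
        raise ValidationError(f"field CSV must contain columns {sorted(required)}")
    if len(frame) != mesh.n_cells:
        raise ValidationError(
            f"field CSV has {len(frame)} rows; mesh has {mesh.n_cells} cells"
        )
    vals = np.zeros((mesh.nr, mesh.nz))
    vals[frame["i"].to_numpy(), frame["j"].to_numpy()] = frame["phi_kg_per_m3"].to_numpy()
    return ConcentrationField(mesh, vals)
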