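"""File output: legacy-VTK snapshots, CSV diagnostics, JSON run manifests.

CSV values are written with ``repr`` round-trip precision so downstream
checks lose nothing.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .diagnostics import DiagnosticsRecord
from .mesh import Mesh

__all__ = ["write_vtk", "write_diagnostics_csv", "write_manifest", "read_manifest"]

_VTK_CELL_TYPE = {"triangle": 5, "rectangle": 9}  # VTK_TRIANGLE, VTK_QUAD


def write_vtk(mesh: Mesh, cell_data: dict, path) -> None:
    """Legacy ASCII VTK unstructured grid with per-cell scalar fields."""
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        "ionfv snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(mesh.nodes)} double",
    ]
    for p in mesh.nodes:
        lines.append(f"{p[0]:.17g} {p[1]:.17g} 0.0")
    nv = mesh.cells.shape[1]
    lines.append(f"CELLS {mesh.n_cells} {mesh.n_cells * (nv + 1)}")
    for c in mesh.cells:
        lines.append(str(nv) + " " + " ".join(str(int(v)) for v in c))
    lines.append(f"CELL_TYPES {mesh.n_cells}")
    ct = _VTK_CELL_TYPE[mesh.cell_shape]
    lines.extend([str(ct)] * mesh.n_cells)
    lines.append(f"CELL_DATA {mesh.n_cells}")
    for name, values in cell_data.items():
        values = np.asarray(values, dtype=float)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.17g}" for v in values)
    path.write_text("\n".join(lines) + "\n")


def write_diagnostics_csv(records: list[DiagnosticsRecord], dt: float, path) -> None:
    path = Path(path)
    if not records:
        path.write_text("")
        return
    n = len(records[0].masses)
    header = (
        ["k", "t", "H", "I", "E"]
        + [f"mass_u{i+1}" for i in range(n)]
        + [f"min_u{i+1}" for i in range(n)]
        + [f"max_u{i+1}" for i in range(n)]
        + ["sum_max", "newton_iters"]
    )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for r in records:
            row = [r.k, repr(r.k * dt), repr(r.entropy)]
            row.append("" if r.entropy_production is None else repr(r.entropy_production))
            row.append("" if r.relative_entropy is None else repr(r.relative_entropy))
            row += [repr(v) for v in r.masses]
            row += [repr(v) for v in r.u_min]
            row += [repr(v) for v in r.u_max]
            row += [repr(r.sum_max), r.newton_iterations]
            w.writerow(row)


def write_manifest(config_dict: dict, seed: int, path) -> None:
    import ionfv

    payload = {
        "config": config_dict,
        "seed": seed,
        "version": getattr(ionfv, "__version__", "unknown"),
        "numpy": np.__version__,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
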