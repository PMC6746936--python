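"""Minimal legacy-VTK (ASCII) writer for the plate mesh and its fields.

Writes an unstructured grid of quadrilaterals with arbitrary point data
(e.g. nodal displacements) and cell data (modulus, density, bin id, risk,
principal strains), viewable in ParaView or any VTK-based tool.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .meshing import PlanarMesh

_VTK_QUAD = 9


def _fmt(values: np.ndarray) -> str:
    return "\n".join(" ".join(f"{v:.9g}" for v in row) for row in values)


def write_vtk(
    path: str | Path,
    mesh: PlanarMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "dxafem plate model",
) -> Path:
    path = Path(path)
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    pts3 = np.column_stack([mesh.nodes, np.zeros(n_pts)])

    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n_pts} float",
        _fmt(pts3),
        f"CELLS {n_cells} {n_cells * 5}",
        "\n".join("4 " + " ".join(map(str, el)) for el in mesh.elements),
        f"CELL_TYPES {n_cells}",
        "\n".join([str(_VTK_QUAD)] * n_cells),
    ]

    if point_data:
        lines.append(f"POINT_DATA {n_pts}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2 and arr.shape[1] in (2, 3):
                vec = np.zeros((n_pts, 3))
                vec[:, : arr.shape[1]] = arr
                lines += [f"VECTORS {name} float", _fmt(vec)]
            else:
                lines += [
                    f"SCALARS {name} float 1",
                    "LOOKUP_TABLE default",
                    _fmt(arr.reshape(-1, 1)),
                ]
    if cell_data:
        lines.append(f"CELL_DATA {n_cells}")
        for name, arr in cell_data.items():
            arr = np.asarray(arr, dtype=float)
            lines += [
                f"SCALARS {name} float 1",
                "LOOKUP_TABLE default",
                _fmt(arr.reshape(-1, 1)),
            ]
    path.write_text("\n".join(lines) + "\n")
    return path
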