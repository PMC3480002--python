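"""Plain-text mesh and field I/O: legacy ASCII VTK and Gmsh 2.2.

Snapshots are legacy VTK unstructured-grid files (``DATASET
UNSTRUCTURED_GRID``, cell type 12 = hexahedron) readable by VisIt and
ParaView.  Meshes can additionally be exchanged as Gmsh 2.2 ASCII ``.msh``
files (element type 5 = 8-node hexahedron).
"""

from __future__ import annotations

import os

import numpy as np

from .mesh import Mesh


def _fmt(arr):
    return "\n".join(" ".join(f"{x:.9g}" for x in row) for row in np.atleast_2d(arr))


def write_vtk(path, points, hexes, point_data=None, cell_data=None,
              title="cardioem snapshot"):
    """Write one legacy ASCII VTK unstructured-grid file.

    ``point_data``/``cell_data`` map names to arrays of shape (n,) (scalars)
    or (n, 3) (vectors).
    """
    points = np.asarray(points, dtype=float)
    hexes = np.asarray(hexes, dtype=int)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(points)} double",
        _fmt(points),
        f"CELLS {len(hexes)} {len(hexes) * 9}",
        "\n".join("8 " + " ".join(str(i) for i in h) for h in hexes),
        f"CELL_TYPES {len(hexes)}",
        "\n".join(["12"] * len(hexes)),
    ]

    def data_section(kind, n, data):
        out = [f"{kind} {n}"]
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2 and arr.shape[1] == 3:
                out.append(f"VECTORS {name} double")
                out.append(_fmt(arr))
            else:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.append("\n".join(f"{x:.9g}" for x in arr.reshape(-1)))
        return out

    if point_data:
        lines += data_section("POINT_DATA", len(points), point_data)
    if cell_data:
        lines += data_section("CELL_DATA", len(hexes), cell_data)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def read_vtk_mesh(path):
    """Read points and hexahedral connectivity back from a legacy VTK file."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0
    points = hexes = None
    while i < len(tokens):
        line = tokens[i].split()
        if line and line[0] == "POINTS":
            n = int(line[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in tokens[i].split())
                i += 1
            points = np.asarray(vals).reshape(n, 3)
            continue
        if line and line[0] == "CELLS":
            e = int(line[1])
            rows = []
            for k in range(e):
                row = [int(x) for x in tokens[i + 1 + k].split()]
                if row[0] != 8:
                    raise ValueError("only hexahedral cells are supported")
                rows.append(row[1:])
            hexes = np.asarray(rows, dtype=int)
            i += e + 1
            continue
        i += 1
    if points is None or hexes is None:
        raise ValueError(f"{path} is not a hexahedral VTK unstructured grid")
    return points, hexes


def write_gmsh(path, mesh: Mesh):
    """Write the reference mesh in Gmsh 2.2 ASCII format."""
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, p in enumerate(mesh.X_ref, start=1):
            fh.write(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"$EndNodes\n$Elements\n{mesh.n_elems}\n")
        for e, h in enumerate(mesh.hexes, start=1):
            nodes = " ".join(str(i + 1) for i in h)
            fh.write(f"{e} 5 2 0 0 {nodes}\n")
        fh.write("$EndElements\n")
    return path


def read_gmsh(path, fiber_vector=(0.0, 1.0, 0.0)) -> Mesh:
    """Read a Gmsh 2.2 hexahedral mesh.

    The format carries no fiber information, so a uniform fiber vector is
    assigned (override per element afterwards if needed); node sets start
    empty.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    nodes, hexes = [], []
    i = 0
    while i < len(lines):
        if lines[i] == "$Nodes":
            n = int(lines[i + 1])
            for k in range(n):
                parts = lines[i + 2 + k].split()
                nodes.append([float(x) for x in parts[1:4]])
            i += n + 2
        elif lines[i] == "$Elements":
            e = int(lines[i + 1])
            for k in range(e):
                parts = [int(x) for x in lines[i + 2 + k].split()]
                if parts[1] != 5:
                    continue  # skip non-hex entities
                ntags = parts[2]
                hexes.append([x - 1 for x in parts[3 + ntags:]])
            i += e + 2
        else:
            i += 1
    fib = np.asarray(fiber_vector, dtype=float)
    fib = fib / np.linalg.norm(fib)
    return Mesh(X_ref=np.asarray(nodes), hexes=np.asarray(hexes, dtype=int),
                a0_field=np.tile(fib, (len(hexes), 1)))


def snapshot_filename(output_dir, index):
    return os.path.join(output_dir, f"snapshot_{index:04d}.vtk")
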