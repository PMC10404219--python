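"""Mesh file I/O: Gmsh MSH v2.2 ASCII and legacy-VTK export.

Only the subset needed for labeled tetrahedral volume meshes is handled:
MSH element type 4 (4-node tetrahedron) with the physical-group tag used
as the tissue label.  Node and element indices are 1-based on disk and
0-based in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .headmodel import TetrahedralMesh

_TET = 4  # Gmsh element type id


def write_msh(mesh: TetrahedralMesh, path) -> None:
    """Write a TetrahedralMesh as Gmsh MSH v2.2 ASCII."""
    path = Path(path)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    if mesh.label_names:
        lines.append("$PhysicalNames")
        lines.append(str(len(mesh.label_names)))
        for lid in sorted(mesh.label_names):
            lines.append(f'3 {lid} "{mesh.label_names[lid]}"')
        lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_nodes))
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.10g} {y:.10g} {z:.10g}")
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(mesh.n_tets))
    for i, (tet, lab) in enumerate(zip(mesh.tets, mesh.tet_label), start=1):
        a, b, c, d = (int(v) + 1 for v in tet)
        lines.append(f"{i} {_TET} 2 {int(lab)} {int(lab)} {a} {b} {c} {d}")
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")
    # sidecar with electrode node sets and phantom metadata, if any
    if mesh.electrode_nodes or mesh.metadata:
        side = {
            "electrode_nodes": {
                k: np.asarray(v).tolist() for k, v in mesh.electrode_nodes.items()
            },
            "metadata": _jsonable(mesh.metadata),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_msh(path) -> TetrahedralMesh:
    """Read a labeled tetrahedral mesh from Gmsh MSH v2.2 ASCII.

    Non-tetrahedral elements are ignored.  The mesh is validated
    (positive volumes after orientation normalisation, no orphan nodes).
    """
    path = Path(path)
    text = path.read_text()
    sections: dict[str, list[str]] = {}
    cur = None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("$End"):
            cur = None
        elif line.startswith("$"):
            cur = line[1:]
            sections[cur] = []
        elif cur is not None:
            sections[cur].append(line)

    if "MeshFormat" not in sections:
        raise ValidationError(f"{path}: not a Gmsh MSH file")
    version = sections["MeshFormat"][0].split()[0]
    if not version.startswith("2"):
        raise ValidationError(f"{path}: unsupported MSH version {version}")

    label_names: dict[int, str] = {}
    for line in sections.get("PhysicalNames", [])[1:]:
        parts = line.split(maxsplit=2)
        if len(parts) == 3:
            label_names[int(parts[1])] = parts[2].strip('"')

    node_lines = sections.get("Nodes", [])
    n_nodes = int(node_lines[0])
    ids = np.empty(n_nodes, dtype=np.int64)
    xyz = np.empty((n_nodes, 3))
    for k, line in enumerate(node_lines[1 : 1 + n_nodes]):
        parts = line.split()
        ids[k] = int(parts[0])
        xyz[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
    id_map = {int(i): k for k, i in enumerate(ids)}

    elem_lines = sections.get("Elements", [])
    n_elem = int(elem_lines[0])
    tets, labels = [], []
    for line in elem_lines[1 : 1 + n_elem]:
        parts = [int(v) for v in line.split()]
        etype, ntags = parts[1], parts[2]
        if etype != _TET:
            continue
        tags = parts[3 : 3 + ntags]
        conn = parts[3 + ntags : 7 + ntags]
        tets.append([id_map[c] for c in conn])
        labels.append(tags[0] if tags else 0)
    if not tets:
        raise ValidationError(f"{path}: no tetrahedral elements")
    tets = np.asarray(tets, dtype=np.int64)
    labels = np.asarray(labels, dtype=np.int64)
    for lid in np.unique(labels):
        label_names.setdefault(int(lid), f"label{lid}")

    # orientation normalisation
    p = xyz[tets]
    vols = np.einsum(
        "ij,ij->i", p[:, 1] - p[:, 0], np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])
    )
    neg = vols < 0
    tets[neg, 0], tets[neg, 1] = tets[neg, 1].copy(), tets[neg, 0].copy()

    electrode_nodes: dict[str, np.ndarray] = {}
    metadata: dict = {}
    side_path = path.with_suffix(path.suffix + ".json")
    if side_path.exists():
        side = json.loads(side_path.read_text())
        electrode_nodes = {
            k: np.asarray(v, dtype=np.int64)
            for k, v in side.get("electrode_nodes", {}).items()
        }
        metadata = side.get("metadata", {})

    mesh = TetrahedralMesh(xyz, tets, labels, label_names, electrode_nodes, metadata)
    mesh.validate()
    return mesh


def write_vtk(mesh: TetrahedralMesh, path, cell_data: dict | None = None) -> None:
    """Legacy-VTK ASCII export (unstructured grid) for 3-D viewers.

    ``cell_data`` maps name -> per-tet array; tissue labels are always
    included.
    """
    path = Path(path)
    out = [
        "# vtk DataFile Version 3.0",
        "phasortacs mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    out.extend(f"{x:.10g} {y:.10g} {z:.10g}" for x, y, z in mesh.nodes)
    out.append(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}")
    out.extend(
        f"4 {int(a)} {int(b)} {int(c)} {int(d)}" for a, b, c, d in mesh.tets
    )
    out.append(f"CELL_TYPES {mesh.n_tets}")
    out.extend(["10"] * mesh.n_tets)
    out.append(f"CELL_DATA {mesh.n_tets}")
    data = {"tissue_label": mesh.tet_label}
    if cell_data:
        data.update(cell_data)
    for name, arr in data.items():
        arr = np.asarray(arr)
        if np.issubdtype(arr.dtype, np.integer):
            out.append(f"SCALARS {name} int 1")
            out.append("LOOKUP_TABLE default")
            out.extend(str(int(v)) for v in arr)
        else:
            out.append(f"SCALARS {name} double 1")
            out.append("LOOKUP_TABLE default")
            out.extend(f"{float(v):.10g}" for v in arr)
    path.write_text("\n".join(out) + "\n")
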