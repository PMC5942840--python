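"""Mesh and field input/output: Gmsh MSH v2.2, VTU (XML) and landmark JSON.

Both formats are written in their plain-text (ASCII) form.  Region labels
travel as Gmsh physical groups / VTU cell data named ``region``; node sets
and landmark indices are serialised to JSON side files since neither
format carries named node sets.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import REGIONS, LabeledTetMesh, LandmarkSet, MeshError

__all__ = [
    "write_msh",
    "read_msh",
    "write_vtu",
    "read_vtu",
    "write_landmarks",
    "read_landmarks",
    "write_node_sets",
    "read_node_sets",
]

_VTK_TETRA = 10


def write_msh(mesh: LabeledTetMesh, path) -> None:
    """Write the labelled mesh as Gmsh MSH v2.2 (ASCII, 1-based ids)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write("$PhysicalNames\n%d\n" % len(REGIONS))
        for i, name in enumerate(REGIONS):
            fh.write(f'3 {i + 1} "{name}"\n')
        fh.write("$EndPhysicalNames\n")
        fh.write("$Nodes\n%d\n" % mesh.n_nodes)
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {x:.16g} {y:.16g} {z:.16g}\n")
        fh.write("$EndNodes\n")
        fh.write("$Elements\n%d\n" % mesh.n_tets)
        for e, (tet, rid) in enumerate(zip(mesh.tets, mesh.region_ids), start=1):
            a, b, c, d = (int(v) + 1 for v in tet)
            fh.write(f"{e} 4 2 {int(rid) + 1} {int(rid) + 1} {a} {b} {c} {d}\n")
        fh.write("$EndElements\n")


def read_msh(path) -> LabeledTetMesh:
    """Read a tetrahedral MSH v2.2 file written by :func:`write_msh`."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    names: dict[int, str] = {}
    nodes, tets, rids = [], [], []
    for line in it:
        if line == "$PhysicalNames":
            n = int(next(it))
            for _ in range(n):
                dim, tag, name = next(it).split(maxsplit=2)
                names[int(tag)] = name.strip('"')
            next(it)  # $EndPhysicalNames
        elif line == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append([float(v) for v in parts[1:4]])
            next(it)
        elif line == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype, ntags = int(parts[1]), int(parts[2])
                if etype != 4:
                    raise MeshError(f"unsupported element type {etype} (tets only)")
                phys = int(parts[3])
                conn = [int(v) - 1 for v in parts[3 + ntags :]]
                name = names.get(phys, REGIONS[phys - 1] if phys <= 4 else None)
                if name not in REGIONS:
                    raise MeshError(f"unknown physical region tag {phys}")
                tets.append(conn)
                rids.append(REGIONS.index(name))
            next(it)
    if not nodes or not tets:
        raise MeshError(f"no tetrahedral mesh found in {path}")
    return LabeledTetMesh(
        nodes=np.asarray(nodes, dtype=float),
        tets=np.asarray(tets, dtype=np.int64),
        region_ids=np.asarray(rids, dtype=np.int64),
    )


def _ascii_array(values, fmt="%.16g") -> str:
    arr = np.asarray(values)
    return "\n".join(" ".join(fmt % v for v in np.atleast_1d(row)) for row in arr)


def write_vtu(
    mesh: LabeledTetMesh,
    path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh (plus optional nodal/cell fields) as ASCII XML VTU.

    ``point_data`` arrays may be scalar (n_nodes,) or vector (n_nodes, 3);
    the region label is always written as cell data named ``region``.
    """
    cell_data = {"region": mesh.region_ids, **(cell_data or {})}
    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid, "Piece",
        NumberOfPoints=str(mesh.n_nodes), NumberOfCells=str(mesh.n_tets),
    )
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    da.text = _ascii_array(mesh.nodes)
    cells = ET.SubElement(piece, "Cells")
    for name, arr, typ in (
        ("connectivity", mesh.tets.ravel(), "Int64"),
        ("offsets", 4 * (np.arange(mesh.n_tets) + 1), "Int64"),
        ("types", np.full(mesh.n_tets, _VTK_TETRA), "UInt8"),
    ):
        d = ET.SubElement(cells, "DataArray", type=typ, Name=name, format="ascii")
        d.text = _ascii_array(arr, "%d")
    if point_data:
        pd_el = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            d = ET.SubElement(
                pd_el, "DataArray", type="Float64", Name=name,
                NumberOfComponents=str(ncomp), format="ascii",
            )
            d.text = _ascii_array(arr)
    cd_el = ET.SubElement(piece, "CellData")
    for name, arr in cell_data.items():
        d = ET.SubElement(
            cd_el, "DataArray", type="Int64" if np.issubdtype(
                np.asarray(arr).dtype, np.integer) else "Float64",
            Name=name, format="ascii",
        )
        d.text = _ascii_array(arr, "%d" if np.issubdtype(
            np.asarray(arr).dtype, np.integer) else "%.16g")
    ET.ElementTree(root).write(path, xml_declaration=True)


def read_vtu(path) -> tuple[LabeledTetMesh, dict[str, np.ndarray]]:
    """Read an ASCII VTU tet mesh; returns (mesh, point_data)."""
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    nodes = np.fromstring(
        piece.find("Points/DataArray").text, sep=" "
    ).reshape(-1, 3)
    arrays = {d.get("Name"): d for d in piece.find("Cells")}
    types = np.fromstring(arrays["types"].text, sep=" ", dtype=int)
    if not np.all(types == _VTK_TETRA):
        raise MeshError("VTU contains non-tetrahedral cells")
    tets = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=int).reshape(-1, 4)
    rids = np.zeros(len(tets), dtype=np.int64)
    cd = piece.find("CellData")
    if cd is not None:
        for d in cd:
            if d.get("Name") == "region":
                rids = np.fromstring(d.text, sep=" ", dtype=float).astype(np.int64)
    point_data: dict[str, np.ndarray] = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for d in pd_el:
            ncomp = int(d.get("NumberOfComponents", "1"))
            arr = np.fromstring(d.text, sep=" ")
            point_data[d.get("Name")] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
    return (
        LabeledTetMesh(nodes=nodes, tets=tets, region_ids=rids),
        point_data,
    )


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    Path(path).write_text(
        json.dumps({k: int(v) for k, v in landmarks.indices.items()}, indent=2) + "\n"
    )


def read_landmarks(path) -> LandmarkSet:
    return LandmarkSet(indices={k: int(v) for k, v in json.loads(
        Path(path).read_text()).items()})


def write_node_sets(mesh: LabeledTetMesh, path) -> None:
    Path(path).write_text(
        json.dumps({k: np.asarray(v).tolist() for k, v in mesh.node_sets.items()})
        + "\n"
    )


def read_node_sets(path) -> dict[str, np.ndarray]:
    return {
        k: np.asarray(v, dtype=int)
        for k, v in json.loads(Path(path).read_text()).items()
    }
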