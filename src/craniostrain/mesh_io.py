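"""Readers and writers for labelled tet meshes: Gmsh MSH 4.1, VTU, Abaqus INP.

All three are plain-text formats.  MSH and VTU round-trip bit-consistently
(coordinates are printed with 17 significant digits); INP is export-only.

Conventions
-----------
* VTU: material labels are stored as an Int32 cell array ``material_id``
  whose DataArray carries a ``LabelMap`` attribute (``"0:bone;1:pdl"``);
  node sets become Int8 point arrays named ``nset:<name>``.
* MSH: one element block per contiguous run of equal material (preserving
  global element order); material names go to ``$PhysicalNames``; node sets
  are stored in a custom ``$NodeSets`` section, which conforming readers
  skip as an unknown section.
* INP: 1-based ids, one ``*ELEMENT``/``ELSET`` block per material, node
  sets as ``*NSET`` (names sanitised to INP rules).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from craniostrain.mesh import LabeledTetMesh, MeshError

__all__ = ["read_mesh", "write_mesh", "read_cell_data"]

_F = "%.17g"  # round-trips float64 exactly

# gmsh tet10 midside order differs from VTK in the last two edges
_GMSH_TET10_COLS = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]


def _fmt(fmt: str | None, path) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in ("msh", "vtu", "inp"):
        raise MeshError(f"unsupported mesh format: {fmt!r}")
    return fmt


def write_mesh(mesh: LabeledTetMesh, path, fmt: str | None = None,
               cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a mesh; format from ``fmt`` or the file suffix.

    ``cell_data`` (name -> per-element float array) is supported for VTU
    only, where it becomes additional CellData arrays.
    """
    fmt = _fmt(fmt, path)
    if cell_data and fmt != "vtu":
        raise MeshError("cell_data output is only supported for VTU")
    if fmt == "vtu":
        _write_vtu(mesh, path, cell_data or {})
    elif fmt == "msh":
        _write_msh(mesh, path)
    else:
        _write_inp(mesh, path)


def read_mesh(path, fmt: str | None = None) -> LabeledTetMesh:
    """Read a mesh written by :func:`write_mesh` (MSH or VTU)."""
    fmt = _fmt(fmt, path)
    if fmt == "vtu":
        return _read_vtu(path)
    if fmt == "msh":
        return _read_msh(path)
    raise MeshError("INP import is not supported (export only)")


# ---------------------------------------------------------------------------
# VTU


def _ascii(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.dtype.kind == "f":
        return "\n".join(" ".join(_F % v for v in row) for row in np.atleast_2d(a))
    return "\n".join(" ".join(str(v) for v in row) for row in np.atleast_2d(a))


def _write_vtu(mesh: LabeledTetMesh, path, cell_data: dict) -> None:
    labels = sorted(set(mesh.material.tolist()))
    lab2id = {l: i for i, l in enumerate(labels)}
    mat_id = np.array([lab2id[l] for l in mesh.material], dtype=np.int32)
    labelmap = ";".join(f"{i}:{l}" for l, i in lab2id.items())
    npts, ncel = mesh.n_nodes, mesh.n_elements
    nper = mesh.elements.shape[1]
    vtk_type = 10 if nper == 4 else 24

    out = []
    w = out.append
    w('<?xml version="1.0"?>')
    w('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    w("<UnstructuredGrid>")
    w(f'<Piece NumberOfPoints="{npts}" NumberOfCells="{ncel}">')
    w("<Points>")
    w('<DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">')
    w(_ascii(mesh.nodes))
    w("</DataArray>")
    w("</Points>")
    w("<Cells>")
    w('<DataArray type="Int64" Name="connectivity" format="ascii">')
    w(_ascii(mesh.elements))
    w("</DataArray>")
    w('<DataArray type="Int64" Name="offsets" format="ascii">')
    w(_ascii((np.arange(1, ncel + 1) * nper)[:, None]))
    w("</DataArray>")
    w('<DataArray type="UInt8" Name="types" format="ascii">')
    w(_ascii(np.full((ncel, 1), vtk_type, dtype=np.uint8)))
    w("</DataArray>")
    w("</Cells>")
    w("<CellData>")
    w(f'<DataArray type="Int32" Name="material_id" format="ascii" LabelMap="{labelmap}">')
    w(_ascii(mat_id[:, None]))
    w("</DataArray>")
    for name, arr in cell_data.items():
        arr = np.asarray(arr, dtype=float)
        if len(arr) != ncel:
            raise MeshError(f"cell_data {name!r} has wrong length")
        w(f'<DataArray type="Float64" Name="{name}" format="ascii">')
        w(_ascii(arr[:, None] if arr.ndim == 1 else arr))
        w("</DataArray>")
    w("</CellData>")
    w("<PointData>")
    for name, ids in mesh.node_sets.items():
        mask = np.zeros((npts, 1), dtype=np.int8)
        mask[ids] = 1
        w(f'<DataArray type="Int8" Name="nset:{name}" format="ascii">')
        w(_ascii(mask))
        w("</DataArray>")
    w("</PointData>")
    w("</Piece>")
    w("</UnstructuredGrid>")
    w("</VTKFile>")
    Path(path).write_text("\n".join(out) + "\n")


def _read_vtu(path) -> LabeledTetMesh:
    root = ET.parse(str(path)).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise MeshError(f"{path}: not a VTU unstructured grid")

    def arr(xpath, dtype=float):
        el = piece.find(xpath)
        return np.array(el.text.split(), dtype=dtype), el

    pts, _ = arr('./Points/DataArray[@Name="Points"]')
    nodes = pts.reshape(-1, 3)
    conn, _ = arr('./Cells/DataArray[@Name="connectivity"]')
    offs, _ = arr('./Cells/DataArray[@Name="offsets"]')
    nper = int(offs[0]) if len(offs) else 4
    elements = conn.astype(np.int64).reshape(-1, nper)
    mat_raw, mat_el = arr('./CellData/DataArray[@Name="material_id"]')
    labelmap = mat_el.get("LabelMap", "")
    id2lab = {}
    for part in filter(None, labelmap.split(";")):
        i, l = part.split(":", 1)
        id2lab[int(i)] = l
    material = np.array([id2lab.get(int(i), str(int(i))) for i in mat_raw], dtype="U16")
    node_sets = {}
    for el in piece.findall("./PointData/DataArray"):
        name = el.get("Name", "")
        if name.startswith("nset:"):
            mask = np.array(el.text.split(), dtype=int)
            node_sets[name[5:]] = np.nonzero(mask)[0].astype(np.int64)
    return LabeledTetMesh(nodes, elements, material, node_sets)


def read_cell_data(path) -> dict[str, np.ndarray]:
    """Float CellData arrays of a VTU written by :func:`write_mesh`."""
    root = ET.parse(str(path)).getroot()
    piece = root.find("./UnstructuredGrid/Piece")
    if piece is None:
        raise MeshError(f"{path}: not a VTU unstructured grid")
    ncel = int(piece.get("NumberOfCells"))
    out = {}
    for el in piece.findall("./CellData/DataArray"):
        if el.get("type") != "Float64":
            continue
        a = np.array(el.text.split(), dtype=float)
        out[el.get("Name")] = a if a.size == ncel else a.reshape(ncel, -1)
    return out


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 ASCII


def _material_runs(material: np.ndarray):
    """Contiguous (start, stop, label) runs preserving element order."""
    runs = []
    start = 0
    for i in range(1, len(material) + 1):
        if i == len(material) or material[i] != material[start]:
            runs.append((start, i, str(material[start])))
            start = i
    return runs


def _write_msh(mesh: LabeledTetMesh, path) -> None:
    labels = sorted(set(mesh.material.tolist()))
    phys = {l: i + 1 for i, l in enumerate(labels)}
    runs = _material_runs(mesh.material)
    etype = 4 if mesh.order == 1 else 11
    elems = mesh.elements if mesh.order == 1 else mesh.elements[:, _GMSH_TET10_COLS]
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)

    out = []
    w = out.append
    w("$MeshFormat\n4.1 0 8\n$EndMeshFormat")
    w("$PhysicalNames")
    w(str(len(labels)))
    for l in labels:
        w(f'3 {phys[l]} "{l}"')
    w("$EndPhysicalNames")
    w("$Entities")
    w(f"0 0 0 {len(labels)}")
    for l in labels:
        w(f"{phys[l]} " + " ".join(_F % v for v in (*lo, *hi)) + f" 1 {phys[l]} 0")
    w("$EndEntities")
    w("$Nodes")
    n = mesh.n_nodes
    w(f"1 {n} 1 {n}")
    w(f"3 {phys[labels[0]]} 0 {n}")
    for i in range(n):
        w(str(i + 1))
    for p in mesh.nodes:
        w(" ".join(_F % v for v in p))
    w("$EndNodes")
    w("$Elements")
    w(f"{len(runs)} {mesh.n_elements} 1 {mesh.n_elements}")
    for start, stop, lab in runs:
        w(f"3 {phys[lab]} {etype} {stop - start}")
        for e in range(start, stop):
            w(" ".join(str(v) for v in [e + 1, *(elems[e] + 1)]))
    w("$EndElements")
    w("$NodeSets")
    w(str(len(mesh.node_sets)))
    for name, ids in mesh.node_sets.items():
        w(f'"{name}" {len(ids)}')
        w(" ".join(str(i + 1) for i in ids) if len(ids) else "")
    w("$EndNodeSets")
    Path(path).write_text("\n".join(out) + "\n")


def _read_msh(path) -> LabeledTetMesh:
    text = Path(path).read_text().splitlines()
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(text) and text[j].strip() != f"$End{name}":
                body.append(text[j])
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1

    phys2lab = {}
    if "PhysicalNames" in sections:
        for line in sections["PhysicalNames"][1:]:
            parts = line.split(maxsplit=2)
            phys2lab[int(parts[1])] = parts[2].strip().strip('"')

    body = sections["Nodes"]
    nblocks = int(body[0].split()[0])
    row = 1
    ids, coords = [], []
    for _ in range(nblocks):
        _, _tag, _, nn = body[row].split()
        nn = int(nn)
        row += 1
        ids.extend(int(v) for v in body[row : row + nn])
        row += nn
        for line in body[row : row + nn]:
            coords.append([float(v) for v in line.split()[:3]])
        row += nn
    order = np.argsort(ids)
    nodes = np.asarray(coords)[order]
    remap = {ids[k]: rank for rank, k in enumerate(order)}

    body = sections["Elements"]
    nblocks = int(body[0].split()[0])
    row = 1
    elems, mats = [], []
    for _ in range(nblocks):
        _, etag, etype, ne = (int(v) for v in body[row].split())
        row += 1
        lab = phys2lab.get(etag, str(etag))
        for line in body[row : row + ne]:
            conn = [remap[int(v)] for v in line.split()[1:]]
            elems.append(conn)
            mats.append(lab)
        row += ne
    elements = np.asarray(elems, dtype=np.int64)
    if elements.shape[1] == 10:
        inv = np.argsort(_GMSH_TET10_COLS)
        elements = elements[:, inv]

    node_sets = {}
    if "NodeSets" in sections:
        body = sections["NodeSets"]
        nsets = int(body[0])
        row = 1
        for _ in range(nsets):
            name, cnt = body[row].rsplit(maxsplit=1)
            name = name.strip().strip('"')
            row += 1
            vals = body[row].split() if int(cnt) else []
            node_sets[name] = np.array([remap[int(v)] for v in vals], dtype=np.int64)
            row += 1
    return LabeledTetMesh(nodes, elements, np.array(mats, dtype="U16"), node_sets)


# ---------------------------------------------------------------------------
# Abaqus INP (export only)


def _inp_name(name: str) -> str:
    safe = "".join(ch if ch.isalnum() or ch in "_-" else "-" for ch in name)
    return safe.upper()


def _write_inp(mesh: LabeledTetMesh, path) -> None:
    eltype = "C3D4" if mesh.order == 1 else "C3D10"
    out = ["*HEADING", "craniostrain labelled tetrahedral mesh", "*NODE"]
    for i, p in enumerate(mesh.nodes):
        out.append(f"{i + 1}, " + ", ".join(_F % v for v in p))
    for lab in sorted(set(mesh.material.tolist())):
        out.append(f"*ELEMENT, TYPE={eltype}, ELSET=MAT_{_inp_name(lab)}")
        for e in np.nonzero(mesh.material == lab)[0]:
            out.append(f"{e + 1}, " + ", ".join(str(v + 1) for v in mesh.elements[e]))
    for name, ids in mesh.node_sets.items():
        out.append(f"*NSET, NSET={_inp_name(name)}")
        for k in range(0, len(ids), 16):
            out.append(", ".join(str(i + 1) for i in ids[k : k + 16]))
    Path(path).write_text("\n".join(out) + "\n")
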