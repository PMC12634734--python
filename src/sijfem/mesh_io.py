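"""Mesh file I/O: ASCII VTU and Gmsh MSH 4.1, plus landmark CSV sidecars.

Both writers embed the tetrahedra and the named surface patches; VTU
stores patches as triangle cells with a ``patch_id`` cell-data array (and
the name table in FieldData), MSH stores them as physical surface groups.
Element fields (density, modulus, bone id) ride along as VTU cell data.

Landmarks are written to a ``<stem>.landmarks.csv`` sidecar
(columns: name, x, y, z, side) next to the mesh file and read back
automatically; write -> read round-trips nodes, connectivity, patches and
landmarks exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import pandas as pd

from .mesh import REQUIRED_PATCHES, MeshError, TetMesh

_VTK_TET = 10
_VTK_TRI = 5
_MSH_TET = 4
_MSH_TRI = 2


def _landmark_side(name: str) -> str:
    if "_left" in name:
        return "left"
    if "_right" in name:
        return "right"
    return "mid"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".landmarks.csv")


def _write_landmarks(mesh: TetMesh, path: Path) -> None:
    rows = [
        {
            "name": name,
            "x": p[0],
            "y": p[1],
            "z": p[2],
            "side": _landmark_side(name),
            "node": mesh.landmark_nodes.get(name, -1),
        }
        for name, p in mesh.landmarks.items()
    ]
    pd.DataFrame(rows).to_csv(_sidecar(path), index=False)


def _read_landmarks(path: Path):
    sc = _sidecar(path)
    landmarks: dict[str, np.ndarray] = {}
    landmark_nodes: dict[str, int] = {}
    if sc.exists():
        df = pd.read_csv(sc)
        for _, row in df.iterrows():
            landmarks[row["name"]] = np.array([row["x"], row["y"], row["z"]])
            if "node" in df.columns and int(row["node"]) >= 0:
                landmark_nodes[row["name"]] = int(row["node"])
    return landmarks, landmark_nodes


def write_mesh(mesh: TetMesh, path, cell_data: dict | None = None,
               point_data: dict | None = None) -> None:
    """Write a mesh (format from the extension: .vtu or .msh).

    ``cell_data`` holds per-tetrahedron float arrays and ``point_data``
    per-node arrays (scalars or 3-vectors); both are VTU-only.
    """
    path = Path(path)
    if path.suffix == ".vtu":
        _write_vtu(mesh, path, cell_data=cell_data, point_data=point_data)
    elif path.suffix == ".msh":
        _write_msh(mesh, path)
    else:
        raise MeshError(f"unsupported mesh format {path.suffix!r} (use .vtu or .msh)")
    _write_landmarks(mesh, path)


def export_solution_vtu(state, mesh: TetMesh, path,
                        material=None) -> None:
    """Write a solved state for visualization: displacements as point
    data, von Mises stress (and optionally the element modulus) as cell
    data, and nodal contact pressure where defined."""
    pressure = np.zeros(mesh.n_nodes)
    for st in getattr(state, "contact", []):
        pressure[st["nodes"]] = np.maximum(pressure[st["nodes"]], st["pressure"])
    cell_data = {"von_mises": state.stress_von_mises}
    if material is not None:
        cell_data["modulus"] = material.modulus
    write_mesh(
        mesh, path,
        cell_data=cell_data,
        point_data={"displacement": state.u, "contact_pressure": pressure},
    )


def read_mesh(path, validate: bool = True, required=REQUIRED_PATCHES) -> TetMesh:
    """Read a mesh written by :func:`write_mesh` (or a compatible subset)."""
    path = Path(path)
    if path.suffix == ".vtu":
        mesh = _read_vtu(path)
    elif path.suffix == ".msh":
        mesh = _read_msh(path)
    else:
        raise MeshError(f"unsupported mesh format {path.suffix!r} (use .vtu or .msh)")
    mesh.landmarks, mesh.landmark_nodes = _read_landmarks(path)
    if validate:
        missing = [p for p in required if p not in mesh.patches]
        if missing:
            raise MeshError(
                "mesh file is missing required surface patches: "
                + ", ".join(missing)
            )
    return mesh


# ---------------------------------------------------------------------------
# VTU


def _ascii(arr, fmt="{:.17g}") -> str:
    return " ".join(fmt.format(v) for v in np.asarray(arr).ravel())


def _write_vtu(mesh: TetMesh, path: Path, cell_data: dict | None = None,
               point_data: dict | None = None) -> None:
    patch_names = list(mesh.patches)
    n_tets = mesh.n_elements
    tri_cells = [tri for name in patch_names for tri in mesh.patches[name]]
    patch_id = np.concatenate(
        [
            np.full(n_tets, -1, dtype=int),
            np.concatenate(
                [
                    np.full(len(mesh.patches[n]), i, dtype=int)
                    for i, n in enumerate(patch_names)
                ]
            )
            if tri_cells
            else np.empty(0, dtype=int),
        ]
    )
    conn = np.concatenate([mesh.tets.ravel(), np.asarray(tri_cells, dtype=int).ravel()])
    offsets = np.concatenate(
        [4 * np.arange(1, n_tets + 1), 4 * n_tets + 3 * np.arange(1, len(tri_cells) + 1)]
    )
    types = np.concatenate(
        [np.full(n_tets, _VTK_TET), np.full(len(tri_cells), _VTK_TRI)]
    )
    bone = (
        np.concatenate([mesh.elem_bone, np.full(len(tri_cells), -1)])
        if mesh.elem_bone is not None
        else np.full(len(types), -1)
    )

    root = ET.Element(
        "VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian"
    )
    grid = ET.SubElement(root, "UnstructuredGrid")
    fd = ET.SubElement(grid, "FieldData")
    names_json = json.dumps(patch_names).encode()
    fda = ET.SubElement(
        fd, "DataArray", type="Int8", Name="patch_names_json", format="ascii",
        NumberOfTuples=str(len(names_json)),
    )
    fda.text = _ascii(np.frombuffer(names_json, dtype=np.int8), "{:d}")
    piece = ET.SubElement(
        grid, "Piece",
        NumberOfPoints=str(mesh.n_nodes), NumberOfCells=str(len(types)),
    )
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(
        pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii"
    )
    da.text = _ascii(mesh.nodes)
    cells = ET.SubElement(piece, "Cells")
    for name, arr, fmt in (
        ("connectivity", conn, "{:d}"),
        ("offsets", offsets, "{:d}"),
        ("types", types, "{:d}"),
    ):
        d = ET.SubElement(cells, "DataArray", type="Int64", Name=name, format="ascii")
        d.text = _ascii(arr, fmt)
    cd = ET.SubElement(piece, "CellData")
    for name, arr in (("patch_id", patch_id), ("bone_id", bone)):
        d = ET.SubElement(cd, "DataArray", type="Int32", Name=name, format="ascii")
        d.text = _ascii(arr, "{:d}")
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr, dtype=float)
        # tet-level data padded with zeros over the patch triangle cells
        full = np.concatenate([arr, np.zeros(len(tri_cells))])
        d = ET.SubElement(cd, "DataArray", type="Float64", Name=name, format="ascii")
        d.text = _ascii(full)
    if point_data:
        pdata = ET.SubElement(piece, "PointData")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            d = ET.SubElement(
                pdata, "DataArray", type="Float64", Name=name,
                NumberOfComponents=str(ncomp), format="ascii",
            )
            d.text = _ascii(arr)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="unicode")


def _read_vtu(path: Path) -> TetMesh:
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    nodes = np.fromstring(
        piece.find("Points/DataArray").text, sep=" "
    ).reshape(-1, 3)

    def cell_array(name):
        for d in piece.find("Cells"):
            if d.get("Name") == name:
                return np.fromstring(d.text, sep=" ", dtype=np.int64)
        raise MeshError(f"VTU missing Cells array {name!r}")

    conn = cell_array("connectivity")
    offsets = cell_array("offsets")
    types = cell_array("types")

    patch_id = None
    bone = None
    cd = piece.find("CellData")
    if cd is not None:
        for d in cd:
            if d.get("Name") == "patch_id":
                patch_id = np.fromstring(d.text, sep=" ", dtype=np.int64)
            if d.get("Name") == "bone_id":
                bone = np.fromstring(d.text, sep=" ", dtype=np.int64)
    patch_names = []
    fd = root.find(".//FieldData")
    if fd is not None:
        for d in fd:
            if d.get("Name") == "patch_names_json":
                raw = np.fromstring(d.text, sep=" ", dtype=np.int8).tobytes()
                patch_names = json.loads(raw.decode())

    starts = np.concatenate([[0], offsets[:-1]])
    tets = []
    tet_bone = []
    patches: dict[str, list] = {n: [] for n in patch_names}
    for i, (s, e, t) in enumerate(zip(starts, offsets, types)):
        cell = conn[s:e]
        if t == _VTK_TET:
            tets.append(cell)
            if bone is not None:
                tet_bone.append(bone[i])
        elif t == _VTK_TRI and patch_id is not None and patch_id[i] >= 0:
            name = patch_names[patch_id[i]] if patch_names else str(patch_id[i])
            patches.setdefault(name, []).append(cell)
    return TetMesh(
        nodes=nodes,
        tets=np.asarray(tets, dtype=int),
        patches={k: np.asarray(v, dtype=int) for k, v in patches.items() if v},
        elem_bone=np.asarray(tet_bone, dtype=int) if tet_bone else None,
    )


# ---------------------------------------------------------------------------
# Gmsh MSH 4.1 (ASCII subset: one volume entity per bone, one surface
# entity per patch, all nodes in the first volume entity)


def _write_msh(mesh: TetMesh, path: Path) -> None:
    patch_names = list(mesh.patches)
    bones = (
        sorted(set(int(b) for b in mesh.elem_bone))
        if mesh.elem_bone is not None
        else [0]
    )
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    lines.append(str(len(patch_names) + len(bones)))
    for i, name in enumerate(patch_names):
        lines.append(f'2 {i + 1} "{name}"')
    for b in bones:
        lines.append(f'3 {100 + b} "bone_{b}"')
    lines.append("$EndPhysicalNames")

    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    bb = f"{lo[0]:.17g} {lo[1]:.17g} {lo[2]:.17g} {hi[0]:.17g} {hi[1]:.17g} {hi[2]:.17g}"
    lines.append("$Entities")
    lines.append(f"0 0 {len(patch_names)} {len(bones)}")
    for i in range(len(patch_names)):
        lines.append(f"{i + 1} {bb} 1 {i + 1} 0")
    for b in bones:
        lines.append(f"{100 + b} {bb} 1 {100 + b} 0")
    lines.append("$EndEntities")

    n = mesh.n_nodes
    lines.append("$Nodes")
    lines.append(f"1 {n} 1 {n}")
    lines.append(f"3 {100 + bones[0]} 0 {n}")
    lines.extend(str(i + 1) for i in range(n))
    lines.extend(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in mesh.nodes)
    lines.append("$EndNodes")

    blocks = []
    tag = 1
    for i, name in enumerate(patch_names):
        tris = mesh.patches[name]
        rows = [f"{tag + j} " + " ".join(str(v + 1) for v in tri) for j, tri in enumerate(tris)]
        blocks.append((f"2 {i + 1} {_MSH_TRI} {len(tris)}", rows))
        tag += len(tris)
    for b in bones:
        sel = (
            np.flatnonzero(mesh.elem_bone == b)
            if mesh.elem_bone is not None
            else np.arange(mesh.n_elements)
        )
        rows = [
            f"{tag + j} " + " ".join(str(v + 1) for v in mesh.tets[e])
            for j, e in enumerate(sel)
        ]
        blocks.append((f"3 {100 + b} {_MSH_TET} {len(sel)}", rows))
        tag += len(sel)
    total = tag - 1
    lines.append("$Elements")
    lines.append(f"{len(blocks)} {total} 1 {total}")
    for header, rows in blocks:
        lines.append(header)
        lines.extend(rows)
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> TetMesh:
    text = path.read_text().splitlines()
    sections: dict[str, list[str]] = {}
    cur = None
    for line in text:
        line = line.strip()
        if line.startswith("$End"):
            cur = None
        elif line.startswith("$"):
            cur = line[1:]
            sections[cur] = []
        elif cur:
            sections[cur].append(line)

    phys_surface: dict[int, str] = {}
    phys_volume: dict[int, int] = {}
    for line in sections.get("PhysicalNames", [])[1:]:
        dim, tag, name = line.split(maxsplit=2)
        name = name.strip('"')
        if dim == "2":
            phys_surface[int(tag)] = name
        elif dim == "3" and name.startswith("bone_"):
            phys_volume[int(tag)] = int(name.split("_")[1])

    # entity tag -> physical tag
    ent_phys_2d: dict[int, int] = {}
    ent_phys_3d: dict[int, int] = {}
    ent = sections.get("Entities", [])
    if ent:
        np_, nc, ns, nv = (int(v) for v in ent[0].split())
        idx = 1 + np_ + nc
        for line in ent[idx : idx + ns]:
            vals = line.split()
            if int(vals[7]) > 0:
                ent_phys_2d[int(vals[0])] = int(vals[8])
        for line in ent[idx + ns : idx + ns + nv]:
            vals = line.split()
            if int(vals[7]) > 0:
                ent_phys_3d[int(vals[0])] = int(vals[8])

    node_lines = sections["Nodes"]
    nblocks = int(node_lines[0].split()[0])
    coords: dict[int, list[float]] = {}
    i = 1
    for _ in range(nblocks):
        _, _, _, cnt = node_lines[i].split()
        cnt = int(cnt)
        tags = [int(node_lines[i + 1 + j]) for j in range(cnt)]
        for j in range(cnt):
            coords[tags[j]] = [float(v) for v in node_lines[i + 1 + cnt + j].split()[:3]]
        i += 1 + 2 * cnt
    order = sorted(coords)
    remap = {t: k for k, t in enumerate(order)}
    nodes = np.array([coords[t] for t in order])

    elem_lines = sections["Elements"]
    nblocks = int(elem_lines[0].split()[0])
    tets, tet_bone = [], []
    patches: dict[str, list] = {}
    i = 1
    for _ in range(nblocks):
        dim, etag, etype, cnt = (int(v) for v in elem_lines[i].split())
        for j in range(cnt):
            vals = [int(v) for v in elem_lines[i + 1 + j].split()[1:]]
            cell = [remap[v] for v in vals]
            if etype == _MSH_TET:
                tets.append(cell)
                tet_bone.append(phys_volume.get(ent_phys_3d.get(etag, -1), 0))
            elif etype == _MSH_TRI:
                name = phys_surface.get(ent_phys_2d.get(etag, -1))
                if name:
                    patches.setdefault(name, []).append(cell)
        i += 1 + cnt
    return TetMesh(
        nodes=nodes,
        tets=np.asarray(tets, dtype=int),
        patches={k: np.asarray(v, dtype=int) for k, v in patches.items()},
        elem_bone=np.asarray(tet_bone, dtype=int) if tet_bone else None,
    )
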