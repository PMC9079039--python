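"""Hexahedral mesh container and Abaqus-dialect I/O.

Meshes are 8-node trilinear hexahedra in the Abaqus C3D8/C3D8P node
ordering (nodes 1-4 the bottom face counterclockwise seen from above,
5-8 the top face). Coordinates are millimetres in the joint frame:
x = anterior->posterior, y = medial->lateral, z = inferior->superior.

The file format is the flat Abaqus input-deck subset (*NODE, *ELEMENT,
*NSET, *ELSET, *SURFACE); this is deliberately a dialect, not a full deck
parser. Surfaces are stored per Abaqus convention as (element, face label)
pairs with S1..S6 referring to the local faces below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "HexMesh",
    "MeshError",
    "InpParseError",
    "FACE_NODES",
    "shape_functions",
    "shape_gradients",
    "corner_jacobians",
    "read_inp",
    "write_inp",
    "write_vtu",
]

#: Local node indices (0-based) of the six hexahedron faces, Abaqus S1..S6
#: order, each quad oriented so its normal points out of the element.
FACE_NODES = np.array(
    [
        [0, 3, 2, 1],  # S1, bottom (zeta = -1)
        [4, 5, 6, 7],  # S2, top (zeta = +1)
        [0, 1, 5, 4],  # S3
        [1, 2, 6, 5],  # S4
        [2, 3, 7, 6],  # S5
        [3, 0, 4, 7],  # S6
    ]
)

#: Natural coordinates of the 8 corners in Abaqus order.
CORNER_XI = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


class MeshError(ValueError):
    """Invalid mesh topology or geometry."""


class InpParseError(ValueError):
    """Malformed input-deck file; carries the offending line number."""

    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for points ``xi`` of shape (..., 3)."""
    xi = np.asarray(xi, dtype=float)
    g = CORNER_XI  # (8, 3)
    return 0.125 * np.prod(1.0 + xi[..., None, :] * g, axis=-1)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi_j at natural points ``xi``; returns shape (..., 8, 3)."""
    xi = np.asarray(xi, dtype=float)
    g = CORNER_XI
    terms = 1.0 + xi[..., None, :] * g  # (..., 8, 3)
    out = np.empty(terms.shape)
    for j in range(3):
        prod = np.ones(terms.shape[:-1])
        for k in range(3):
            if k != j:
                prod = prod * terms[..., k]
        out[..., j] = 0.125 * g[:, j] * prod
    return out


# gradients at the 8 corners and at the 2x2x2 Gauss points, precomputed
_CORNER_GRADS = shape_gradients(CORNER_XI)  # (8, 8, 3)
GAUSS_XI = CORNER_XI / np.sqrt(3.0)
GAUSS_GRADS = shape_gradients(GAUSS_XI)  # (8, 8, 3)
GAUSS_N = shape_functions(GAUSS_XI)  # (8, 8)
GAUSS_W = np.ones(8)


def corner_jacobians(coords: np.ndarray, elements: np.ndarray) -> np.ndarray:
    """det(J) at the 8 corners of every element; shape (n_elem, 8)."""
    xe = coords[elements]  # (n_elem, 8, 3)
    J = np.einsum("cai,eaj->ecji", _CORNER_GRADS, xe)  # (n_elem, 8corner, 3, 3)
    return np.linalg.det(J)


@dataclass
class HexMesh:
    """Nodes, hexahedral connectivity, named sets, and normalized depth.

    Attributes
    ----------
    coords:
        (n_nodes, 3) float array, mm.
    elements:
        (n_elem, 8) int array of 0-based node indices, Abaqus ordering.
    node_sets:
        name -> sorted int array of node indices.
    face_sets:
        name -> (k, 2) int array of (element index, local face 0..5) pairs.
    h_z:
        (n_elem,) normalized depth in [0, 1]; 0 at the articular surface,
        1 at the cartilage-bone interface.
    """

    coords: np.ndarray
    elements: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    face_sets: dict[str, np.ndarray] = field(default_factory=dict)
    h_z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise MeshError("coords must have shape (n_nodes, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise MeshError("elements must have shape (n_elem, 8)")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.coords)
        ):
            raise MeshError("element connectivity references unknown node ids")
        if self.h_z is None:
            self.h_z = np.zeros(len(self.elements))
        self.h_z = np.asarray(self.h_z, dtype=float)
        if self.h_z.shape != (len(self.elements),):
            raise MeshError("h_z must have one value per element")

    # ------------------------------------------------------------------ geometry

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corner_jacobians(self) -> np.ndarray:
        return corner_jacobians(self.coords, self.elements)

    def check_jacobians(self) -> None:
        detJ = self.corner_jacobians()
        if detJ.min() <= 0:
            bad = np.argwhere(detJ <= 0)[0]
            raise MeshError(
                f"non-positive Jacobian in element {bad[0]} (corner {bad[1]}): {detJ.min():.3e}"
            )

    def element_volumes(self) -> np.ndarray:
        """Exact trilinear volumes by 2x2x2 Gauss quadrature."""
        xe = self.coords[self.elements]
        J = np.einsum("gai,eaj->egji", GAUSS_GRADS, xe)
        return np.linalg.det(J).sum(axis=1)

    def element_centroids(self) -> np.ndarray:
        return self.coords[self.elements].mean(axis=1)

    def face_node_ids(self, face_set: str) -> np.ndarray:
        """(k, 4) node indices of every face in a named face set."""
        fs = self.face_sets[face_set]
        return self.elements[fs[:, 0][:, None], FACE_NODES[fs[:, 1]]]

    def exterior_faces(self) -> np.ndarray:
        """(k, 2) array of (element, local face) pairs on the boundary."""
        faces = {}
        for e in range(self.n_elements):
            for f in range(6):
                key = frozenset(self.elements[e, FACE_NODES[f]].tolist())
                faces.setdefault(key, []).append((e, f))
        ext = [v[0] for v in faces.values() if len(v) == 1]
        return np.array(sorted(ext), dtype=np.int64).reshape(-1, 2)

    def validate_face_sets_exterior(self) -> None:
        ext = {tuple(r) for r in self.exterior_faces()}
        for name, fs in self.face_sets.items():
            for row in fs:
                if tuple(row) not in ext:
                    raise MeshError(f"face set {name!r} contains interior face {tuple(row)}")

    # --------------------------------------------------------------- adjacency

    def vertex_adjacency(self) -> list[np.ndarray]:
        """For each element, the elements sharing >= 1 node (self excluded)."""
        node_to_elems: dict[int, list[int]] = {}
        for e, conn in enumerate(self.elements):
            for n in conn:
                node_to_elems.setdefault(int(n), []).append(e)
        out = []
        for e, conn in enumerate(self.elements):
            nbrs: set[int] = set()
            for n in conn:
                nbrs.update(node_to_elems[int(n)])
            nbrs.discard(e)
            out.append(np.array(sorted(nbrs), dtype=np.int64))
        return out

    def face_adjacency(self) -> list[np.ndarray]:
        """For each element, the elements sharing a full quad face."""
        faces: dict[frozenset, list[int]] = {}
        for e in range(self.n_elements):
            for f in range(6):
                key = frozenset(self.elements[e, FACE_NODES[f]].tolist())
                faces.setdefault(key, []).append(e)
        out: list[set[int]] = [set() for _ in range(self.n_elements)]
        for elems in faces.values():
            if len(elems) == 2:
                a, b = elems
                out[a].add(b)
                out[b].add(a)
        return [np.array(sorted(s), dtype=np.int64) for s in out]

    # ------------------------------------------------------------------- misc

    def translated(self, offset) -> "HexMesh":
        return replace(self, coords=self.coords + np.asarray(offset, dtype=float))

    def copy(self) -> "HexMesh":
        return HexMesh(
            coords=self.coords.copy(),
            elements=self.elements.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            face_sets={k: v.copy() for k, v in self.face_sets.items()},
            h_z=self.h_z.copy(),
        )


# ------------------------------------------------------------------ file I/O

_KNOWN_ELEMENT_TYPES = {"C3D8P", "C3D8", "C3D8RP", "C3D8R"}


def write_inp(mesh: HexMesh, path: str | Path, heading: str = "kneefe hexahedral mesh") -> None:
    """Serialize to the flat Abaqus input-deck subset (1-based ids)."""
    lines = [f"*HEADING", heading]
    lines.append("*NODE")
    for i, (x, y, z) in enumerate(mesh.coords, start=1):
        lines.append(f"{i}, {x:.12g}, {y:.12g}, {z:.12g}")
    lines.append("*ELEMENT, TYPE=C3D8P")
    for e, conn in enumerate(mesh.elements, start=1):
        lines.append(f"{e}, " + ", ".join(str(int(n) + 1) for n in conn))
    for name, ids in sorted(mesh.node_sets.items()):
        lines.append(f"*NSET, NSET={name}")
        for chunk in np.array_split(np.asarray(ids) + 1, max(1, (len(ids) + 15) // 16)):
            if len(chunk):
                lines.append(", ".join(str(int(i)) for i in chunk))
    for name, fs in sorted(mesh.face_sets.items()):
        lines.append(f"*SURFACE, NAME={name}, TYPE=ELEMENT")
        for e, f in fs:
            lines.append(f"{int(e) + 1}, S{int(f) + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_inp(path: str | Path) -> HexMesh:
    """Parse the flat input-deck subset written by :func:`write_inp`.

    Also accepts hand-written decks using the same keywords. Node and
    element ids may be arbitrary positive integers; they are remapped to
    dense 0-based indices preserving id order.
    """
    text = Path(path).read_text().splitlines()
    node_ids: list[int] = []
    node_xyz: list[list[float]] = []
    elem_ids: list[int] = []
    elem_conn: list[list[int]] = []
    nsets: dict[str, list[int]] = {}
    surfaces: dict[str, list[tuple[int, int]]] = {}
    elsets: dict[str, list[int]] = {}

    section = None
    section_name = None
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            parts = [p.strip() for p in line.split(",")]
            keyword = parts[0].upper()
            opts = {}
            for p in parts[1:]:
                if "=" in p:
                    k, v = p.split("=", 1)
                    opts[k.strip().upper()] = v.strip()
            if keyword == "*HEADING":
                section = "heading"
            elif keyword == "*NODE":
                section = "node"
            elif keyword == "*ELEMENT":
                etype = opts.get("TYPE", "").upper()
                if etype not in _KNOWN_ELEMENT_TYPES:
                    raise InpParseError(f"unknown element type {etype!r}", lineno)
                section = "element"
            elif keyword == "*NSET":
                section = "nset"
                section_name = opts.get("NSET")
                if not section_name:
                    raise InpParseError("*NSET without NSET= name", lineno)
                nsets.setdefault(section_name, [])
            elif keyword == "*ELSET":
                section = "elset"
                section_name = opts.get("ELSET")
                if not section_name:
                    raise InpParseError("*ELSET without ELSET= name", lineno)
                elsets.setdefault(section_name, [])
            elif keyword == "*SURFACE":
                section = "surface"
                section_name = opts.get("NAME")
                if not section_name:
                    raise InpParseError("*SURFACE without NAME=", lineno)
                surfaces.setdefault(section_name, [])
            else:
                section = "skip"
            continue
        try:
            if section == "node":
                parts = [p for p in line.replace(",", " ").split()]
                node_ids.append(int(parts[0]))
                node_xyz.append([float(p) for p in parts[1:4]])
            elif section == "element":
                parts = [int(p) for p in line.replace(",", " ").split()]
                if len(parts) != 9:
                    raise InpParseError("hexahedron line must have id + 8 nodes", lineno)
                elem_ids.append(parts[0])
                elem_conn.append(parts[1:])
            elif section == "nset":
                nsets[section_name].extend(int(p) for p in line.replace(",", " ").split())
            elif section == "elset":
                elsets[section_name].extend(int(p) for p in line.replace(",", " ").split())
            elif section == "surface":
                parts = [p.strip() for p in line.split(",")]
                face = parts[1].upper()
                if not (face.startswith("S") and face[1:].isdigit() and 1 <= int(face[1:]) <= 6):
                    raise InpParseError(f"bad face label {face!r}", lineno)
                surfaces[section_name].append((int(parts[0]), int(face[1:]) - 1))
        except InpParseError:
            raise
        except (ValueError, IndexError) as e:
            raise InpParseError(f"cannot parse data line: {e}", lineno) from e

    if not node_ids:
        raise InpParseError("no *NODE section found", len(text))
    if not elem_ids:
        raise InpParseError("no *ELEMENT section found", len(text))

    nid_map = {nid: i for i, nid in enumerate(node_ids)}
    eid_map = {eid: i for i, eid in enumerate(elem_ids)}
    coords = np.array(node_xyz)
    elements = np.array([[nid_map[n] for n in conn] for conn in elem_conn], dtype=np.int64)
    node_sets = {
        name: np.array(sorted(nid_map[n] for n in ids), dtype=np.int64)
        for name, ids in nsets.items()
    }
    face_sets = {
        name: np.array([[eid_map[e], f] for e, f in pairs], dtype=np.int64).reshape(-1, 2)
        for name, pairs in surfaces.items()
    }
    return HexMesh(coords=coords, elements=elements, node_sets=node_sets, face_sets=face_sets)


def write_vtu(
    mesh: HexMesh,
    path: str | Path,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Minimal ASCII VTK unstructured-grid export (hexahedra, cell type 12)."""
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    out = []
    out.append('<?xml version="1.0"?>')
    out.append('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    out.append("<UnstructuredGrid>")
    out.append(f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">')
    out.append('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    out.extend(" ".join(f"{v:.9g}" for v in row) for row in mesh.coords)
    out.append("</DataArray></Points>")
    out.append("<Cells>")
    out.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    out.extend(" ".join(str(int(n)) for n in conn) for conn in mesh.elements)
    out.append("</DataArray>")
    out.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    out.append(" ".join(str(8 * (i + 1)) for i in range(n_cells)))
    out.append("</DataArray>")
    out.append('<DataArray type="UInt8" Name="types" format="ascii">')
    out.append(" ".join("12" for _ in range(n_cells)))
    out.append("</DataArray>")
    out.append("</Cells>")
    out.append("<CellData>")
    cd = dict(cell_data or {})
    cd.setdefault("h_z", mesh.h_z)
    for name, arr in cd.items():
        out.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
        out.append(" ".join(f"{float(v):.9g}" for v in np.asarray(arr).ravel()))
        out.append("</DataArray>")
    out.append("</CellData>")
    if point_data:
        out.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            out.append(
                f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{ncomp}" format="ascii">'
            )
            out.append(" ".join(f"{float(v):.9g}" for v in arr.ravel()))
            out.append("</DataArray>")
        out.append("</PointData>")
    out.append("</Piece></UnstructuredGrid></VTKFile>")
    Path(path).write_text("\n".join(out) + "\n")
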