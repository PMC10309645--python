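"""Tetrahedral meshes and the edge-neighbor operator.

The reconstruction domain is a tetrahedral finite-element mesh: the unknown
fluorescent yield lives on mesh nodes, and the neighbor-expansion step of
NASOLS grows its support set along tetrahedral edges.  This module provides
the mesh container, a structured cube-mesh generator, boundary extraction,
the node adjacency graph, the neighbor operator N(.), and plain-text I/O
(TetGen-style .node/.ele pairs and legacy ASCII VTK).

All node indexing is 0-based internally; 1-based files are detected and
converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TetMesh",
    "NeighborGraph",
    "BoundaryPatch",
    "MeshValidationError",
    "generate_cube_mesh",
    "load_mesh",
    "save_mesh",
    "write_vtk",
    "boundary_patch",
    "edge_adjacency",
    "neighbor_set",
    "connected_components",
]


class MeshValidationError(ValueError):
    """Raised when a mesh violates its structural invariants."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Tetrahedral mesh: node coordinates in mm and 4-node connectivity.

    Parameters
    ----------
    nodes : (N, 3) float array
        Node coordinates in mm.
    elements : (M, 4) int array
        Tetrahedra as node-index 4-tuples, consistently oriented so that
        every signed volume is positive.
    region_label : (M,) int array, optional
        Per-element material/organ id; defaults to a single region 0.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.intp)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshValidationError("nodes must be an (N, 3) array")
        if self.n_nodes < 4:
            raise MeshValidationError("a tetrahedral mesh needs at least 4 nodes")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise MeshValidationError("elements must be an (M, 4) array")
        if self.elements.min(initial=0) < 0 or (
            self.elements.size and self.elements.max() >= self.n_nodes
        ):
            raise MeshValidationError("element refers to a node index out of range")
        if self.region_label is None:
            self.region_label = np.zeros(len(self.elements), dtype=np.intp)
        else:
            self.region_label = np.asarray(self.region_label, dtype=np.intp)
            if self.region_label.shape != (len(self.elements),):
                raise MeshValidationError("region_label must have one entry per element")
        self._orient()

    def _orient(self) -> None:
        """Flip node order where needed so every signed volume is positive."""
        vol = self.signed_volumes()
        if np.any(vol == 0.0):
            bad = int(np.flatnonzero(vol == 0.0)[0])
            raise MeshValidationError(f"degenerate (zero-volume) tetrahedron at element {bad}")
        flip = vol < 0
        if np.any(flip):
            self.elements[flip] = self.elements[flip][:, [0, 2, 1, 3]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def signed_volumes(self) -> np.ndarray:
        """Signed volume of each tetrahedron (mm^3)."""
        p = self.nodes[self.elements]
        return np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0

    def element_volumes(self) -> np.ndarray:
        return np.abs(self.signed_volumes())

    def nodal_volumes(self) -> np.ndarray:
        """Lumped nodal volumes: each tet spreads V/4 onto its vertices."""
        v = np.zeros(self.n_nodes)
        np.add.at(v, self.elements.ravel(), np.repeat(self.element_volumes() / 4.0, 4))
        return v

    def centroid(self) -> np.ndarray:
        return self.nodes.mean(axis=0)


@dataclass
class NeighborGraph:
    """Per-node adjacency over tetrahedral edges (symmetric, loop-free)."""

    adjacency: list[frozenset[int]]

    @property
    def n_nodes(self) -> int:
        return len(self.adjacency)

    def degree(self, k: int) -> int:
        return len(self.adjacency[k])


@dataclass
class BoundaryPatch:
    """Boundary triangles (each owned by exactly one tet) with outward normals."""

    faces: np.ndarray            # (F, 3) node indices
    face_elements: np.ndarray    # (F,) owning element index
    normals: np.ndarray          # (F, 3) unit outward normals
    areas: np.ndarray            # (F,)
    boundary_nodes: np.ndarray   # sorted unique node indices

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_centroids(self, mesh: TetMesh) -> np.ndarray:
        return mesh.nodes[self.faces].mean(axis=1)


# ---------------------------------------------------------------------------
# structured cube generator
# ---------------------------------------------------------------------------

# Freudenthal/Kuhn 6-tet split of the unit hexahedron along the (0,0,0)-(1,1,1)
# diagonal.  Corner local ids are binary (ix + 2*iy + 4*iz).  One fixed split
# rule for every cell keeps the mesh conforming and the adjacency reproducible.
_KUHN_TETS = (
    (0, 1, 3, 7),
    (0, 3, 2, 7),
    (0, 2, 6, 7),
    (0, 6, 4, 7),
    (0, 4, 5, 7),
    (0, 5, 1, 7),
)


def generate_cube_mesh(side_mm: float, spacing_mm: float) -> TetMesh:
    """Structured tetrahedral mesh of a cube ``[0, side]^3``.

    The cube is divided into a regular hexahedral grid with cell size at most
    ``spacing_mm`` and every cell is split into 6 tetrahedra by the fixed
    Kuhn rule, so the output (and its edge adjacency) is deterministic.

    Parameters
    ----------
    side_mm : float
        Edge length of the cube in mm.
    spacing_mm : float
        Desired node spacing in mm; the actual spacing is ``side / ceil(side
        / spacing)`` which never exceeds it.
    """
    if not (side_mm > 0) or not (spacing_mm > 0):
        raise ValueError("side_mm and spacing_mm must be positive")
    if spacing_mm > side_mm:
        raise ValueError("spacing_mm must not exceed side_mm")
    n_cells = int(np.ceil(round(side_mm / spacing_mm, 9)))
    n = n_cells + 1
    axis = np.linspace(0.0, side_mm, n)
    zz, yy, xx = np.meshgrid(axis, axis, axis, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])

    def nid(ix: np.ndarray, iy: np.ndarray, iz: np.ndarray) -> np.ndarray:
        return (iz * n + iy) * n + ix

    ix, iy, iz = np.meshgrid(np.arange(n_cells), np.arange(n_cells),
                             np.arange(n_cells), indexing="ij")
    ix, iy, iz = ix.ravel(), iy.ravel(), iz.ravel()
    corners = np.stack(
        [nid(ix + (c & 1), iy + ((c >> 1) & 1), iz + ((c >> 2) & 1)) for c in range(8)],
        axis=1,
    )
    elements = np.concatenate([corners[:, list(t)] for t in _KUHN_TETS], axis=0)
    return TetMesh(nodes=nodes, elements=elements)


# ---------------------------------------------------------------------------
# boundary and adjacency
# ---------------------------------------------------------------------------

_FACE_LOCAL = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))


def boundary_patch(mesh: TetMesh) -> BoundaryPatch:
    """Extract boundary faces (those belonging to exactly one tetrahedron)."""
    faces = np.concatenate([mesh.elements[:, list(f)] for f in _FACE_LOCAL], axis=0)
    owners = np.tile(np.arange(mesh.n_elements), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_sorted = key[order]
    new_group = np.ones(len(key_sorted), dtype=bool)
    new_group[1:] = np.any(key_sorted[1:] != key_sorted[:-1], axis=1)
    group_id = np.cumsum(new_group) - 1
    counts = np.bincount(group_id)
    unique_mask = counts[group_id] == 1
    sel = order[unique_mask]
    bfaces = faces[sel]
    bowners = owners[sel]

    p = mesh.nodes[bfaces]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    normals = cross / np.linalg.norm(cross, axis=1, keepdims=True)
    # orient outward: away from the owning tet's fourth vertex
    fc = p.mean(axis=1)
    ec = mesh.nodes[mesh.elements[bowners]].mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, fc - ec) < 0
    normals[flip] *= -1.0
    bnodes = np.unique(bfaces)
    return BoundaryPatch(faces=bfaces, face_elements=bowners, normals=normals,
                         areas=areas, boundary_nodes=bnodes)


def edge_adjacency(mesh: TetMesh) -> NeighborGraph:
    """Node adjacency graph: j ~ k iff some tetrahedron contains both.

    This is the edge-connection relationship that defines the neighbor
    operator used for support expansion.
    """
    pairs = []
    el = mesh.elements
    for a in range(4):
        for b in range(a + 1, 4):
            pairs.append(el[:, [a, b]])
    e = np.concatenate(pairs, axis=0)
    e = np.unique(np.sort(e, axis=1), axis=0)
    adjacency: list[set[int]] = [set() for _ in range(mesh.n_nodes)]
    for a, b in e:
        adjacency[a].add(int(b))
        adjacency[b].add(int(a))
    return NeighborGraph(adjacency=[frozenset(s) for s in adjacency])


def complete_graph(n: int) -> NeighborGraph:
    """All-to-all adjacency; with it, neighbor-restricted selection reduces
    to unrestricted selection over every column."""
    full = frozenset(range(n))
    return NeighborGraph(adjacency=[full - {k} for k in range(n)])


def neighbor_set(graph: NeighborGraph, support: Iterable[int]) -> set[int]:
    """Neighbor operator N(S): union of edge neighbors of S, excluding S.

    Members of S are excluded because selections are drawn from N(S) and then
    united with S — keeping S inside would waste selections on columns that
    are already in the support.
    """
    support = set(int(k) for k in support)
    for k in support:
        if k < 0 or k >= graph.n_nodes:
            raise IndexError(f"node index {k} out of range")
    out: set[int] = set()
    for k in support:
        out |= graph.adjacency[k]
    return out - support


def connected_components(graph: NeighborGraph, subset: Iterable[int]) -> list[set[int]]:
    """Partition ``subset`` into maximal edge-connected groups (BFS)."""
    subset = set(int(k) for k in subset)
    for k in subset:
        if k < 0 or k >= graph.n_nodes:
            raise IndexError(f"node index {k} out of range")
    seen: set[int] = set()
    comps: list[set[int]] = []
    for start in sorted(subset):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            nxt: list[int] = []
            for k in frontier:
                for j in graph.adjacency[k]:
                    if j in subset and j not in comp:
                        comp.add(j)
                        nxt.append(j)
            frontier = nxt
        seen |= comp
        comps.append(comp)
    return comps


# ---------------------------------------------------------------------------
# I/O: TetGen-style .node/.ele pair and legacy ASCII VTK
# ---------------------------------------------------------------------------

def _read_rows(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            rows.append(line.split())
    return rows


def _load_node_ele(node_path: Path) -> TetMesh:
    ele_path = node_path.with_suffix(".ele")
    if not ele_path.exists():
        raise FileNotFoundError(f"companion element file not found: {ele_path}")
    nrows = _read_rows(node_path)
    n_nodes = int(nrows[0][0])
    body = nrows[1 : 1 + n_nodes]
    if len(body) != n_nodes:
        raise MeshValidationError("node file shorter than its declared node count")
    node_ids = np.array([int(r[0]) for r in body])
    nodes = np.array([[float(x) for x in r[1:4]] for r in body])

    erows = _read_rows(ele_path)
    n_ele = int(erows[0][0])
    nodes_per = int(erows[0][1]) if len(erows[0]) > 1 else 4
    if nodes_per != 4:
        raise MeshValidationError(
            f"only 4-node tetrahedra are supported, file declares {nodes_per}-node elements"
        )
    ebody = erows[1 : 1 + n_ele]
    if len(ebody) != n_ele:
        raise MeshValidationError("element file shorter than its declared element count")
    elements = np.array([[int(x) for x in r[1:5]] for r in ebody])
    region = None
    if all(len(r) >= 6 for r in ebody):
        region = np.array([int(r[5]) for r in ebody])

    # 1-based files are detected by the minimum printed index
    offset = int(min(node_ids.min(), elements.min()))
    if offset not in (0, 1):
        raise MeshValidationError(f"unsupported index base {offset}")
    elements = elements - offset
    remap = np.full(int(node_ids.max()) - offset + 1, -1, dtype=np.intp)
    remap[node_ids - offset] = np.arange(n_nodes)
    if np.any(elements < 0) or np.any(elements >= len(remap)) or np.any(remap[elements] < 0):
        raise MeshValidationError("element refers to an undeclared node id")
    return TetMesh(nodes=nodes, elements=remap[elements], region_label=region)


def _load_vtk(path: Path) -> TetMesh:
    lines = path.read_text().splitlines()
    i, nodes, elements = 0, None, None
    while i < len(lines):
        tok = lines[i].split()
        if tok and tok[0] == "POINTS":
            n = int(tok[1])
            flat: list[float] = []
            i += 1
            while len(flat) < 3 * n:
                flat.extend(float(x) for x in lines[i].split())
                i += 1
            nodes = np.array(flat).reshape(n, 3)
            continue
        if tok and tok[0] == "CELLS":
            m = int(tok[1])
            cells = []
            i += 1
            for _ in range(m):
                row = [int(x) for x in lines[i].split()]
                if row[0] != 4:
                    raise MeshValidationError("VTK cell is not a 4-node tetrahedron")
                cells.append(row[1:5])
                i += 1
            elements = np.array(cells)
            continue
        if tok and tok[0] == "CELL_TYPES":
            m = int(tok[1])
            types = []
            i += 1
            while len(types) < m:
                types.extend(int(x) for x in lines[i].split())
                i += 1
            if any(t != 10 for t in types):
                raise MeshValidationError("VTK file contains non-tetrahedral cells")
            continue
        i += 1
    if nodes is None or elements is None:
        raise MeshValidationError("VTK file lacks POINTS or CELLS sections")
    return TetMesh(nodes=nodes, elements=elements)


def load_mesh(path: str | Path, format: str = "auto") -> TetMesh:
    """Load a tetrahedral mesh from a .node/.ele pair or a legacy ASCII VTK file.

    ``path`` may point at either file of a node/ele pair.  1-based files are
    auto-detected by their minimum index and converted to 0-based.
    """
    path = Path(path)
    if format == "auto":
        format = "vtk" if path.suffix.lower() == ".vtk" else "node_ele"
    if format == "node_ele":
        if path.suffix == ".ele":
            path = path.with_suffix(".node")
        return _load_node_ele(path)
    if format == "vtk":
        return _load_vtk(path)
    raise ValueError(f"unknown mesh format {format!r}")


def save_mesh(mesh: TetMesh, path: str | Path) -> None:
    """Write a TetGen-style 1-based .node/.ele pair (``path`` names the .node)."""
    path = Path(path)
    if path.suffix != ".node":
        path = path.with_suffix(".node")
    with open(path, "w") as fh:
        fh.write(f"{mesh.n_nodes} 3 0 0\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    with open(path.with_suffix(".ele"), "w") as fh:
        fh.write(f"{mesh.n_elements} 4 1\n")
        for i, (el, lab) in enumerate(zip(mesh.elements, mesh.region_label), start=1):
            fh.write(f"{i} {el[0] + 1} {el[1] + 1} {el[2] + 1} {el[3] + 1} {lab}\n")


def write_vtk(mesh: TetMesh, path: str | Path,
              point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write a legacy ASCII VTK unstructured grid, optionally with nodal scalars.

    The reconstruction is conventionally exported with a point-data scalar
    named ``yield``.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfmtrecon mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"CELLS {mesh.n_elements} {5 * mesh.n_elements}\n")
        for el in mesh.elements:
            fh.write(f"4 {el[0]} {el[1]} {el[2]} {el[3]}\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        for _ in range(mesh.n_elements):
            fh.write("10\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (mesh.n_nodes,):
                    raise ValueError(f"point_data {name!r} must have one value per node")
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    fh.write(f"{v:.17g}\n")
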