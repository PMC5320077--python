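"""Surface and volume mesh containers with standard-format I/O.

Triangulated surfaces (the mesher's input) are held in :class:`TriSurface`,
an oriented manifold-with-boundary mesh whose boundary loops identify the
equator ring and the optic-nerve-head (ONH) canal ring of a sclera shell.
Hexahedral shell meshes are held in :class:`HexMesh` and can be written as
VTK unstructured grids (VTU) or Abaqus input decks (INP) with per-element
material orientations.

Coordinates are millimetres throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "TriSurface",
    "BoundaryLoop",
    "HexMesh",
    "read_triangle_surface",
    "write_triangle_surface",
    "extract_boundary_loops",
    "write_hex_mesh",
    "read_vtu",
    "closest_point_on_surface",
    "HEX_EDGES",
    "HEX_FACES",
]

# Canonical hexahedron connectivity conventions (shared by the mesher, the FE
# solver and both writers).  Corner nodes 0-7 follow the usual (ξ,η,ζ) = ±1
# layout; the 12 edges listed here define the mid-edge node order 8-19 of a
# 20-node serendipity element.  This order coincides with both the VTK
# quadratic-hexahedron and the Abaqus C3D20 conventions, so the writers apply
# an identity permutation (kept explicit for clarity).
HEX_EDGES = np.array(
    [
        (0, 1), (1, 2), (2, 3), (3, 0),
        (4, 5), (5, 6), (6, 7), (7, 4),
        (0, 4), (1, 5), (2, 6), (3, 7),
    ],
    dtype=np.intp,
)

# Six quad faces, each wound so the right-hand normal points out of the cell.
HEX_FACES = np.array(
    [
        (0, 4, 7, 3),  # xi = -1
        (1, 2, 6, 5),  # xi = +1
        (0, 1, 5, 4),  # eta = -1
        (3, 7, 6, 2),  # eta = +1
        (0, 3, 2, 1),  # zeta = -1
        (4, 5, 6, 7),  # zeta = +1
    ],
    dtype=np.intp,
)


class MeshError(ValueError):
    """Raised for topologically or geometrically invalid mesh input."""


@dataclass
class BoundaryLoop:
    """Closed cycle of boundary vertices, ordered along directed boundary edges."""

    vertices: np.ndarray  # (k,) vertex indices, cycle implied (last -> first)
    points: np.ndarray  # (k, 3) coordinates
    arc_length: np.ndarray = field(init=False)  # (k+1,) cumulative, [0 .. total]

    def __post_init__(self) -> None:
        closed = np.vstack([self.points, self.points[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Position at arc-length parameter ``s`` (wrapped to the loop length)."""
        s = np.atleast_1d(np.asarray(s, dtype=float)) % self.total_length
        idx = np.searchsorted(self.arc_length, s, side="right") - 1
        idx = np.clip(idx, 0, len(self.vertices) - 1)
        s0 = self.arc_length[idx]
        seg_len = self.arc_length[idx + 1] - s0
        t = np.where(seg_len > 0, (s - s0) / np.where(seg_len > 0, seg_len, 1.0), 0.0)
        closed = np.vstack([self.points, self.points[:1]])
        out = closed[idx] * (1 - t)[:, None] + closed[idx + 1] * t[:, None]
        return out if out.shape[0] > 1 else out[0]


class TriSurface:
    """Oriented triangulated open surface (manifold with boundary).

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array
    repair_orientation : bool
        Flip triangles as needed so every interior edge is traversed in
        opposite directions by its two triangles. Raises if the surface is
        non-orientable.
    """

    def __init__(self, vertices, triangles, repair_orientation: bool = True):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(triangles, dtype=np.intp)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError("triangles must be (m, 3)")
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise MeshError("triangle index out of range")
        used = np.zeros(len(self.vertices), dtype=bool)
        used[self.triangles.ravel()] = True
        if not used.all():
            raise MeshError("unreferenced vertices present")
        self._check_degenerate()
        self._edge_tables()
        if repair_orientation:
            self._repair_orientation()
            self._edge_tables()  # rebuild after possible flips
        self._check_orientation()
        self._normals = None
        self._kdtree = None

    # -- validation ---------------------------------------------------------

    def _check_degenerate(self) -> None:
        v = self.vertices
        t = self.triangles
        cr = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        area2 = np.linalg.norm(cr, axis=1)
        scale = np.maximum(
            np.linalg.norm(v[t[:, 1]] - v[t[:, 0]], axis=1)
            * np.linalg.norm(v[t[:, 2]] - v[t[:, 0]], axis=1),
            1e-300,
        )
        if np.any(area2 / scale < 1e-12):
            raise MeshError("degenerate (zero-area) triangle present")

    def _edge_tables(self) -> None:
        t = self.triangles
        # directed halfedges in winding order
        he = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        self._halfedges = he
        self._halfedge_tri = np.tile(np.arange(len(t)), 3)
        und = np.sort(he, axis=1)
        uniq, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
        if np.any(counts > 2):
            raise MeshError("non-manifold edge (>= 3 incident triangles)")
        self._edges = uniq  # (E, 2) undirected, sorted
        self._edge_counts = counts
        self._halfedge_edge = inv
        # map edge -> incident triangles (up to 2), vectorized via sort by edge id
        order = np.argsort(inv, kind="stable")
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        inc = np.full((len(uniq), 2), -1, dtype=np.intp)
        inc[:, 0] = self._halfedge_tri[order[starts]]
        two = counts == 2
        inc[two, 1] = self._halfedge_tri[order[starts[two] + 1]]
        self._edge_tris = inc
        self._halfedge_order = order
        self._edge_starts = starts

    def _repair_orientation(self) -> None:
        t = self.triangles
        m = len(t)
        # adjacency via shared undirected edges
        adj: list[list[int]] = [[] for _ in range(m)]
        for e, (ta, tb) in enumerate(self._edge_tris):
            if tb >= 0:
                adj[ta].append(tb)
                adj[tb].append(ta)
        visited = np.zeros(m, dtype=bool)
        flipped = np.zeros(m, dtype=bool)

        def directed_edges(tri_idx: int, flip: bool) -> set[tuple[int, int]]:
            a, b, c = t[tri_idx]
            if flip:
                a, c = c, a
            return {(a, b), (b, c), (c, a)}

        for seed in range(m):
            if visited[seed]:
                continue
            stack = [seed]
            visited[seed] = True
            while stack:
                cur = stack.pop()
                cur_edges = directed_edges(cur, flipped[cur])
                for nb in adj[cur]:
                    nb_edges = directed_edges(nb, False)
                    # consistent orientation: shared edge traversed oppositely,
                    # i.e. the neighbour must NOT contain any of cur's directed edges
                    same = bool(cur_edges & nb_edges)
                    want_flip = same
                    if not visited[nb]:
                        visited[nb] = True
                        flipped[nb] = want_flip
                        stack.append(nb)
                    elif flipped[nb] != want_flip:
                        raise MeshError("surface is non-orientable")
        if flipped.any():
            f = self.triangles[flipped]
            self.triangles[flipped] = f[:, ::-1]

    def _check_orientation(self) -> None:
        interior = self._edge_counts == 2
        if not interior.any():
            return
        # interior edges must be traversed oppositely by their two halfedges
        he = self._halfedges
        starts = self._edge_starts[interior]
        h0 = self._halfedge_order[starts]
        h1 = self._halfedge_order[starts + 1]
        same = np.all(he[h0] == he[h1], axis=1)
        if same.any():
            raise MeshError("inconsistent triangle orientation")

    # -- derived geometry ---------------------------------------------------

    @property
    def triangle_normals(self) -> np.ndarray:
        """(m, 3) unit normals from the triangle winding."""
        if self._normals is None:
            v = self.vertices
            t = self.triangles
            cr = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
            self._normals = cr / np.linalg.norm(cr, axis=1, keepdims=True)
        return self._normals

    @property
    def boundary_edge_mask(self) -> np.ndarray:
        return self._edge_counts == 1

    @property
    def edges(self) -> np.ndarray:
        """(E, 2) undirected unique edges, each row sorted."""
        return self._edges

    def edge_triangles(self, edge_index: int) -> np.ndarray:
        return self._edge_tris[edge_index]

    def triangle_neighbors(self) -> np.ndarray:
        """(m, 3) neighbour triangle across each winding edge (or -1 on boundary)."""
        m = len(self.triangles)
        out = np.full((m, 3), -1, dtype=np.intp)
        for h in range(3 * m):
            tri = self._halfedge_tri[h]
            e = self._halfedge_edge[h]
            ta, tb = self._edge_tris[e]
            nb = tb if ta == tri else ta
            out[tri, h // m] = nb
        return out

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.triangles, process=False)


def read_triangle_surface(path, fmt: str = "auto") -> TriSurface:
    """Read an OFF / PLY / STL triangle surface.

    Vertex order is preserved for indexed formats (OFF, PLY). STL stores
    triangle soup, so identical corner coordinates are merged on load.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in {"off", "ply", "stl"}:
        raise MeshError(f"unsupported surface format: {fmt}")
    mesh = trimesh.load(str(path), file_type=fmt, process=False)
    if not isinstance(mesh, trimesh.Trimesh):
        raise MeshError(f"{path} did not parse to a triangle mesh")
    if fmt == "stl":
        mesh.merge_vertices()
    faces = np.asarray(mesh.faces)
    if faces.size == 0:
        raise MeshError(f"{path} contains no triangles")
    return TriSurface(np.asarray(mesh.vertices, dtype=float), faces)


def write_triangle_surface(surface: TriSurface, path, fmt: str = "auto") -> None:
    path = Path(path)
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    mesh = surface.as_trimesh()
    if fmt == "ply":
        data = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
        path.write_bytes(data)
    else:
        mesh.export(str(path), file_type=fmt)


def extract_boundary_loops(surface: TriSurface) -> list[BoundaryLoop]:
    """Boundary loops sorted by descending total arc length.

    For a sclera shell the first loop is the equator ring and the last the
    ONH canal ring. Loop direction follows the triangle winding (the induced
    boundary orientation).
    """
    he = surface._halfedges
    bmask = surface.boundary_edge_mask[surface._halfedge_edge]
    bhe = he[bmask]  # directed boundary edges
    if len(bhe) == 0:
        return []
    nxt: dict[int, int] = {}
    for a, b in bhe:
        if a in nxt:
            raise MeshError("non-simple boundary (vertex with boundary degree != 2)")
        nxt[int(a)] = int(b)
    loops = []
    remaining = set(nxt)
    while remaining:
        start = min(remaining)
        cyc = [start]
        remaining.discard(start)
        cur = nxt[start]
        while cur != start:
            if cur not in remaining:
                raise MeshError("non-simple boundary (open or branching chain)")
            cyc.append(cur)
            remaining.discard(cur)
            cur = nxt[cur]
        idx = np.array(cyc, dtype=np.intp)
        loops.append(BoundaryLoop(idx, surface.vertices[idx]))
    loops.sort(key=lambda lp: -lp.total_length)
    return loops


def closest_point_on_surface(
    surface: TriSurface, points: np.ndarray, k: int = 32
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest points on a triangle surface.

    A KD-tree over triangle centroids prefilters ``k`` candidate triangles per
    query; the exact point-to-triangle projection is then evaluated on the
    candidates. Returns ``(closest_points, distances, triangle_ids)``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    v = surface.vertices
    t = surface.triangles
    if surface._kdtree is None:
        centroids = v[t].mean(axis=1)
        surface._kdtree = cKDTree(centroids)
    k = min(k, len(t))
    _, cand = surface._kdtree.query(points, k=k)
    cand = np.atleast_2d(cand)
    n = len(points)
    tri_pts = v[t[cand.ravel()]]  # (n*k, 3, 3)
    q = np.repeat(points, k, axis=0)
    cp = trimesh.triangles.closest_point(tri_pts, q)
    d = np.linalg.norm(cp - q, axis=1).reshape(n, k)
    best = np.argmin(d, axis=1)
    rows = np.arange(n)
    closest = cp.reshape(n, k, 3)[rows, best]
    return closest, d[rows, best], cand[rows, best]


@dataclass
class HexMesh:
    """Hexahedral mesh (uniformly 8- or 20-node elements).

    ``face_sets`` map a name to an (f, 2) array of (element index, local face
    id) pairs, with local faces per :data:`HEX_FACES`. ``node_sets`` map a
    name to node indices. ``frames`` holds one 3x3 material frame per element
    (rows x, y, z in global coordinates) when assigned.
    """

    nodes: np.ndarray  # (n, 3) mm
    elements: np.ndarray  # (m, 8) or (m, 20)
    region: np.ndarray | None = None  # (m,) int labels
    frames: np.ndarray | None = None  # (m, 3, 3)
    node_sets: dict = field(default_factory=dict)
    face_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.elements = np.ascontiguousarray(self.elements, dtype=np.intp)
        if self.elements.ndim != 2 or self.elements.shape[1] not in (8, 20):
            raise MeshError("elements must be (m, 8) or (m, 20)")
        if self.elements.size and self.elements.max() >= len(self.nodes):
            raise MeshError("element node index out of range")

    @property
    def order(self) -> int:
        return 8 if self.elements.shape[1] == 8 else 20

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def face_nodes(self, elem: int, face: int) -> np.ndarray:
        """Node indices of a local face: 4 corners, plus 4 mid-edge for order 20."""
        conn = self.elements[elem]
        corners = conn[HEX_FACES[face]]
        if self.order == 8:
            return corners
        loc = HEX_FACES[face]
        mids = []
        for i in range(4):
            a, b = loc[i], loc[(i + 1) % 4]
            eid = _edge_index(a, b)
            mids.append(conn[8 + eid])
        return np.concatenate([corners, mids])


_EDGE_LOOKUP = {}
for _i, (_a, _b) in enumerate(HEX_EDGES):
    _EDGE_LOOKUP[(int(_a), int(_b))] = _i
    _EDGE_LOOKUP[(int(_b), int(_a))] = _i


def _edge_index(a: int, b: int) -> int:
    return _EDGE_LOOKUP[(int(a), int(b))]


# -- volume writers ---------------------------------------------------------

_VTK_HEX = 12
_VTK_QHEX = 25
# identity permutations internal -> dialect (both dialects share our order)
_VTU_PERM_8 = np.arange(8)
_VTU_PERM_20 = np.arange(20)
_INP_PERM_8 = np.arange(8)
_INP_PERM_20 = np.arange(20)


def write_hex_mesh(mesh: HexMesh, path, dialect: str = "auto") -> None:
    """Write a hex mesh as VTU (XML unstructured grid) or Abaqus INP.

    The INP writer emits one element set and solid section per region label
    and, when frames are present, one ``*ORIENTATION`` record per element
    carrying the first two material axes.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = {".vtu": "vtu", ".inp": "inp"}.get(path.suffix.lower(), "vtu")
    if dialect.lower() in ("vtu",):
        _write_vtu(mesh, path)
    elif dialect.lower() in ("inp", "abaqus_inp", "abaqus"):
        _write_inp(mesh, path)
    else:
        raise MeshError(f"unknown dialect {dialect!r}")


def _write_vtu(mesh: HexMesh, path: Path) -> None:
    perm = _VTU_PERM_8 if mesh.order == 8 else _VTU_PERM_20
    ctype = _VTK_HEX if mesh.order == 8 else _VTK_QHEX
    conn = mesh.elements[:, perm]
    n, m = mesh.n_nodes, mesh.n_elements
    lines = []
    lines.append('<?xml version="1.0"?>')
    lines.append('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    lines.append("<UnstructuredGrid>")
    lines.append(f'<Piece NumberOfPoints="{n}" NumberOfCells="{m}">')
    lines.append("<Points>")
    lines.append('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    lines.extend(" ".join(f"{x:.17g}" for x in row) for row in mesh.nodes)
    lines.append("</DataArray>")
    lines.append("</Points>")
    lines.append("<Cells>")
    lines.append('<DataArray type="Int64" Name="connectivity" format="ascii">')
    lines.extend(" ".join(str(i) for i in row) for row in conn)
    lines.append("</DataArray>")
    lines.append('<DataArray type="Int64" Name="offsets" format="ascii">')
    lines.append(" ".join(str((i + 1) * mesh.order) for i in range(m)))
    lines.append("</DataArray>")
    lines.append('<DataArray type="UInt8" Name="types" format="ascii">')
    lines.append(" ".join(str(ctype) for _ in range(m)))
    lines.append("</DataArray>")
    lines.append("</Cells>")
    if mesh.region is not None:
        lines.append("<CellData>")
        lines.append('<DataArray type="Int32" Name="region" format="ascii">')
        lines.append(" ".join(str(int(r)) for r in mesh.region))
        lines.append("</DataArray>")
        lines.append("</CellData>")
    lines.append("</Piece>")
    lines.append("</UnstructuredGrid>")
    lines.append("</VTKFile>")
    path.write_text("\n".join(lines) + "\n")


def read_vtu(path) -> HexMesh:
    """Minimal ascii-VTU reader for round-trip checks (hex cells only)."""
    import xml.etree.ElementTree as ET

    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    coords = np.array(pts.text.split(), dtype=float).reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.findall("Cells/DataArray")}
    conn = np.array(arrays["connectivity"].text.split(), dtype=int)
    offsets = np.array(arrays["offsets"].text.split(), dtype=int)
    types = np.array(arrays["types"].text.split(), dtype=int)
    if not (np.all(types == _VTK_HEX) or np.all(types == _VTK_QHEX)):
        raise MeshError("read_vtu supports uniform hexahedral cells only")
    order = 8 if types[0] == _VTK_HEX else 20
    if np.any(np.diff(offsets) != order) or offsets[0] != order:
        raise MeshError("inconsistent cell offsets")
    elements = conn.reshape(-1, order)
    region = None
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd.findall("DataArray"):
            if da.get("Name") == "region":
                region = np.array(da.text.split(), dtype=int)
    return HexMesh(coords, elements, region=region)


def _write_inp(mesh: HexMesh, path: Path) -> None:
    if mesh.frames is not None and len(mesh.frames) != mesh.n_elements:
        raise MeshError("frames, when present, must cover every element")
    etype = "C3D8" if mesh.order == 8 else "C3D20"
    perm = _INP_PERM_8 if mesh.order == 8 else _INP_PERM_20
    region = mesh.region if mesh.region is not None else np.zeros(mesh.n_elements, dtype=int)
    out = []
    out.append("*HEADING")
    out.append("harmonichex export")
    out.append("*NODE")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        out.append(f"{i}, {x:.10g}, {y:.10g}, {z:.10g}")
    for rid in np.unique(region):
        out.append(f"*ELEMENT, TYPE={etype}, ELSET=REGION-{int(rid)}")
        for e in np.nonzero(region == rid)[0]:
            ids = mesh.elements[e, perm] + 1
            nums = ", ".join(str(int(i)) for i in ids)
            # Abaqus datalines cap at 16 entries; split 20-node rows
            if mesh.order == 20:
                first = ", ".join(str(int(i)) for i in ids[:10])
                rest = ", ".join(str(int(i)) for i in ids[10:])
                out.append(f"{e + 1}, {first},")
                out.append(rest)
            else:
                out.append(f"{e + 1}, {nums}")
    if mesh.frames is not None:
        for e in range(mesh.n_elements):
            x_ax, y_ax = mesh.frames[e, 0], mesh.frames[e, 1]
            out.append(f"*ORIENTATION, NAME=ORI-{e + 1}, DEFINITION=COORDINATES")
            out.append(
                ", ".join(f"{c:.10g}" for c in np.concatenate([x_ax, y_ax]))
            )
    for rid in np.unique(region):
        out.append(f"*SOLID SECTION, ELSET=REGION-{int(rid)}, MATERIAL=MAT-{int(rid)}")
    path.write_text("\n".join(out) + "\n")
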