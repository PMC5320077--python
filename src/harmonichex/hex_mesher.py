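"""Hexahedral shell meshing from matched structured surface grids.

The outer and inner surface grids (N circumferential x M meridional, built
by :mod:`harmonichex.surface_tracing`) are joined through interpolated
interior node layers into ``N * (M-1) * n_layers`` hexahedra.  8-node cells
can be upgraded to 20-node serendipity cells whose surface mid-edge nodes
are projected back onto the source triangulations, so every boundary node —
corner and mid-edge — lies exactly on the input model.

Mesh quality is reported as per-edge dihedral-angle distortion: for each of
the 12 edges of a hexahedron, the angle between its two adjacent (bilinear)
faces is evaluated at the shared edge midpoint and compared with the perfect
90 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .harmonic_field import gradient, loop_constraints, solve_harmonic
from .mesh_io import (
    HEX_EDGES,
    HEX_FACES,
    HexMesh,
    TriSurface,
    closest_point_on_surface,
    extract_boundary_loops,
)
from .surface_tracing import (
    StructuredQuadGrid,
    build_surface_grid,
    match_inner_phase,
    sample_seeds,
    trace_streamline,
)

__all__ = [
    "QualityReport",
    "MeshedShell",
    "interpolate_middle_layer",
    "assemble_hex_mesh",
    "convert_to_20node",
    "scaled_jacobians",
    "dihedral_quality",
    "generate_shell_mesh",
]

QUALITY_BINS = np.array([0.0, 10.0, 20.0, 30.0, 40.0, 50.0, np.inf])


@dataclass
class QualityReport:
    """Dihedral-angle-distortion statistics of a hexahedral mesh (degrees)."""

    distortions: np.ndarray  # (12 * n_elements,)
    n_elements: int
    n_nodes: int

    @property
    def histogram(self) -> np.ndarray:
        counts, _ = np.histogram(self.distortions, bins=QUALITY_BINS)
        return counts / len(self.distortions)

    @property
    def mean(self) -> float:
        return float(self.distortions.mean())

    @property
    def maximum(self) -> float:
        return float(self.distortions.max())

    def fraction_below(self, degrees: float) -> float:
        return float(np.mean(self.distortions < degrees))

    def as_dict(self) -> dict:
        labels = ["0-10", "10-20", "20-30", "30-40", "40-50", ">=50"]
        return {
            "elements": self.n_elements,
            "nodes": self.n_nodes,
            "mean_deg": self.mean,
            "max_deg": self.maximum,
            "histogram": dict(zip(labels, self.histogram.tolist())),
            "fraction_below_20_deg": self.fraction_below(20.0),
        }


def interpolate_middle_layer(
    outer: StructuredQuadGrid, inner: StructuredQuadGrid
) -> StructuredQuadGrid:
    """Midpoint layer between two congruent surface grids."""
    if outer.nodes.shape != inner.nodes.shape:
        raise ValueError("outer and inner grids must share N and M")
    return StructuredQuadGrid(0.5 * (outer.nodes + inner.nodes), outer.levels.copy())


def assemble_hex_mesh(
    outer: StructuredQuadGrid,
    inner: StructuredQuadGrid,
    n_layers: int = 2,
) -> HexMesh:
    """Join outer and inner grids through ``n_layers`` element layers.

    Interior node layers are even linear interpolants between matched outer
    and inner nodes (``n_layers=2`` inserts the single middle layer).  Node
    sets ``on_outer_surface``/``on_inner_surface``, ``equator_ring`` and
    ``onh_ring`` and face sets ``inner_surface``/``outer_surface`` are
    populated.  Raises if any element has a nonpositive corner scaled
    Jacobian.
    """
    if outer.nodes.shape != inner.nodes.shape:
        raise ValueError("grids must be congruent")
    if n_layers < 1:
        raise ValueError("need at least one element layer")
    N, M = outer.N, outer.M
    L = n_layers + 1  # node layers, 0 = outer .. L-1 = inner
    ts = np.linspace(0.0, 1.0, L)
    layers = (1 - ts)[:, None, None, None] * outer.nodes + ts[:, None, None, None] * inner.nodes
    nodes = layers.reshape(-1, 3)  # id = l*N*M + i*M + j

    def nid(l, i, j):
        return l * N * M + (i % N) * M + j

    elems = []
    inner_faces = []
    outer_faces = []
    for l in range(n_layers):
        for i in range(N):
            for j in range(M - 1):
                bottom = [nid(l, i, j), nid(l, i + 1, j), nid(l, i + 1, j + 1), nid(l, i, j + 1)]
                top = [nid(l + 1, i, j), nid(l + 1, i + 1, j), nid(l + 1, i + 1, j + 1), nid(l + 1, i, j + 1)]
                e = len(elems)
                elems.append(bottom + top)
                if l == 0:
                    outer_faces.append((e, 4))  # zeta = -1 face on outer grid
                if l == n_layers - 1:
                    inner_faces.append((e, 5))  # zeta = +1 face on inner grid
    elements = np.array(elems, dtype=np.intp)
    mesh = HexMesh(nodes, elements)
    sj = scaled_jacobians(mesh)
    if np.median(sj) < 0:  # convention flip: swap bottom/top faces globally
        elements = elements[:, [4, 5, 6, 7, 0, 1, 2, 3]]
        outer_faces = [(e, 5) for e, _ in outer_faces]
        inner_faces = [(e, 4) for e, _ in inner_faces]
        mesh = HexMesh(nodes, elements)
        sj = scaled_jacobians(mesh)
    if sj.min() <= 0:
        bad = np.nonzero(sj.min(axis=1) <= 0)[0]
        raise ValueError(f"inverted elements (scaled Jacobian <= 0): {bad[:20].tolist()}")
    lidx = np.arange(L)[:, None, None]
    iidx = np.arange(N)[None, :, None]
    jidx = np.arange(M)[None, None, :]
    ids = (lidx * N * M + iidx * M + jidx)
    mesh.node_sets = {
        "on_outer_surface": ids[0].ravel(),
        "on_inner_surface": ids[L - 1].ravel(),
        "equator_ring": ids[:, :, 0].ravel(),
        "onh_ring": ids[:, :, M - 1].ravel(),
    }
    mesh.face_sets = {
        "inner_surface": np.array(inner_faces, dtype=np.intp),
        "outer_surface": np.array(outer_faces, dtype=np.intp),
    }
    return mesh


def convert_to_20node(
    mesh: HexMesh,
    outer: TriSurface | None = None,
    inner: TriSurface | None = None,
) -> HexMesh:
    """Insert one shared mid-edge node per unique element edge.

    Mid-nodes of edges whose endpoints both lie on the outer (resp. inner)
    surface are projected onto the closest point of that surface; all other
    mid-nodes are exact segment midpoints.  Node sets propagate: a mid-node
    joins every set that contains both its endpoints.
    """
    if mesh.order != 8:
        raise ValueError("mesh is already 20-node")
    elems = mesh.elements
    m = len(elems)
    ea = elems[:, HEX_EDGES[:, 0]]  # (m, 12)
    eb = elems[:, HEX_EDGES[:, 1]]
    und = np.sort(np.stack([ea.ravel(), eb.ravel()], axis=-1), axis=1)
    uniq, inv = np.unique(und, axis=0, return_inverse=True)
    nmid = len(uniq)
    n0 = mesh.n_nodes
    mids = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    edge_len = np.linalg.norm(mesh.nodes[uniq[:, 0]] - mesh.nodes[uniq[:, 1]], axis=1)

    def project(surface: TriSurface, set_name: str):
        onset = np.zeros(n0, dtype=bool)
        onset[mesh.node_sets[set_name]] = True
        sel = onset[uniq[:, 0]] & onset[uniq[:, 1]]
        if not sel.any():
            return
        proj, dist, _ = closest_point_on_surface(surface, mids[sel])
        moved = np.linalg.norm(proj - mids[sel], axis=1)
        if np.any(moved > 0.5 * edge_len[sel]):
            raise ValueError("mid-node projection moved farther than half the edge length")
        mids[sel] = proj

    if outer is not None and "on_outer_surface" in mesh.node_sets:
        project(outer, "on_outer_surface")
    if inner is not None and "on_inner_surface" in mesh.node_sets:
        project(inner, "on_inner_surface")

    # boundary-ring edges: mid-nodes go onto the boundary loop polyline itself
    # (the surface projection above would pull them into the adjacent facet
    # interior, off the ring), keeping the mesh boundary on the input boundary
    def project_ring(surface: TriSurface, surf_set: str, ring_set: str, loop_pick):
        loops = extract_boundary_loops(surface)
        if len(loops) < 2:
            return
        loop = loop_pick(loops)
        onsurf = np.zeros(n0, dtype=bool)
        onsurf[mesh.node_sets[surf_set]] = True
        onring = np.zeros(n0, dtype=bool)
        onring[mesh.node_sets[ring_set]] = True
        both = onsurf & onring
        sel = both[uniq[:, 0]] & both[uniq[:, 1]]
        if not sel.any():
            return
        pts = loop.points
        nxt = np.roll(pts, -1, axis=0)
        ab = nxt - pts
        denom = np.maximum(np.sum(ab * ab, axis=1), 1e-300)
        for k in np.nonzero(sel)[0]:
            p = mids[k]
            t = np.clip(np.sum((p - pts) * ab, axis=1) / denom, 0.0, 1.0)
            proj = pts + t[:, None] * ab
            mids[k] = proj[int(np.argmin(np.linalg.norm(proj - p, axis=1)))]

    for surf, surf_set in ((outer, "on_outer_surface"), (inner, "on_inner_surface")):
        if surf is None or surf_set not in mesh.node_sets:
            continue
        if "equator_ring" in mesh.node_sets:
            project_ring(surf, surf_set, "equator_ring", lambda lps: lps[0])
        if "onh_ring" in mesh.node_sets:
            project_ring(surf, surf_set, "onh_ring", lambda lps: lps[-1])

    nodes = np.vstack([mesh.nodes, mids])
    elements = np.concatenate([elems, n0 + inv.reshape(m, 12)], axis=1)
    out = HexMesh(nodes, elements, region=mesh.region, frames=mesh.frames,
                  face_sets=dict(mesh.face_sets))
    for name, idx in mesh.node_sets.items():
        onset = np.zeros(n0, dtype=bool)
        onset[idx] = True
        both = onset[uniq[:, 0]] & onset[uniq[:, 1]]
        out.node_sets[name] = np.concatenate([idx, n0 + np.nonzero(both)[0]])
    return out


# corner natural coordinates (xi, eta, zeta)
_CORNERS = np.array(
    [
        (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
        (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
    ],
    dtype=float,
)


def _trilinear_deriv(natural: np.ndarray) -> np.ndarray:
    """(k, 8, 3) derivatives of the 8 trilinear shape functions at points."""
    natural = np.atleast_2d(natural)
    k = len(natural)
    out = np.empty((k, 8, 3))
    for a, (xa, ya, za) in enumerate(_CORNERS):
        x, y, z = natural[:, 0], natural[:, 1], natural[:, 2]
        out[:, a, 0] = 0.125 * xa * (1 + y * ya) * (1 + z * za)
        out[:, a, 1] = 0.125 * ya * (1 + x * xa) * (1 + z * za)
        out[:, a, 2] = 0.125 * za * (1 + x * xa) * (1 + y * ya)
    return out


_CORNER_DERIV = _trilinear_deriv(_CORNERS)  # (8, 8, 3)


def scaled_jacobians(mesh: HexMesh) -> np.ndarray:
    """(m, 8) corner scaled Jacobians of the trilinear corner shape.

    For 20-node meshes the metric is evaluated on the 8 corner nodes.
    """
    coords = mesh.nodes[mesh.elements[:, :8]]  # (m, 8, 3)
    J = np.einsum("cad,mak->mcdk", _CORNER_DERIV, coords)  # (m, 8, 3, 3) rows=d/dnat
    det = np.linalg.det(J)
    norms = np.linalg.norm(J, axis=3)  # row norms
    denom = norms[..., 0] * norms[..., 1] * norms[..., 2]
    return det / np.maximum(denom, 1e-300)


# --- dihedral quality -------------------------------------------------------

def _face_param_tables():
    """For each hex edge: its two adjacent faces and the (u, v) midpoint params."""
    tables = []
    for a, b in HEX_EDGES:
        entry = []
        for fidx, face in enumerate(HEX_FACES):
            face = list(face)
            if a in face and b in face:
                ia, ib = face.index(a), face.index(b)
                if (ia + 1) % 4 != ib and (ib + 1) % 4 != ia:
                    continue  # diagonal, not an edge of this face
                uv = {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (1.0, 1.0), 3: (0.0, 1.0)}
                ua, va = uv[ia]
                ub, vb = uv[ib]
                entry.append((fidx, 0.5 * (ua + ub), 0.5 * (va + vb)))
        assert len(entry) == 2
        tables.append(entry)
    return tables


_EDGE_FACES = _face_param_tables()


def _face_normal(coords: np.ndarray, face: int, u: float, v: float) -> np.ndarray:
    """Outward bilinear-face normal at (u, v) for all elements: (m, 3)."""
    idx = HEX_FACES[face]
    P = coords[:, idx]  # (m, 4, 3)
    dNu = np.array([-(1 - v), (1 - v), v, -v])
    dNv = np.array([-(1 - u), -u, u, (1 - u)])
    Xu = np.einsum("a,mak->mk", dNu, P)
    Xv = np.einsum("a,mak->mk", dNv, P)
    n = np.cross(Xu, Xv)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    if np.any(norm < 1e-300):
        raise ValueError("degenerate face (zero normal)")
    return n / norm


def dihedral_quality(mesh: HexMesh) -> QualityReport:
    """Per-edge dihedral-angle distortions |angle - 90 deg| for every element.

    The dihedral angle at an edge is the interior angle between its two
    adjacent bilinear faces, computed from outward face normals evaluated at
    the shared edge midpoint; a perfect cube scores exactly zero on all 12
    edges.
    """
    coords = mesh.nodes[mesh.elements[:, :8]]
    m = len(coords)
    dist = np.empty((m, 12))
    for e, ((f1, u1, v1), (f2, u2, v2)) in enumerate(_EDGE_FACES):
        n1 = _face_normal(coords, f1, u1, v1)
        n2 = _face_normal(coords, f2, u2, v2)
        cosang = np.clip(np.sum(n1 * n2, axis=1), -1.0, 1.0)
        interior = 180.0 - np.degrees(np.arccos(cosang))
        dist[:, e] = np.abs(interior - 90.0)
    return QualityReport(dist.ravel(), m, mesh.n_nodes)


# --- end-to-end shell meshing ----------------------------------------------

@dataclass
class MeshedShell:
    """Bundle of the meshing pipeline's products for one two-surface shell."""

    mesh: HexMesh
    outer: TriSurface
    inner: TriSurface
    field_outer: np.ndarray
    field_inner: np.ndarray
    grid_outer: StructuredQuadGrid
    grid_inner: StructuredQuadGrid
    levels: np.ndarray


def _surface_grid(surface: TriSurface, N: int, M: int, seeds: np.ndarray | None = None):
    loops = extract_boundary_loops(surface)
    if len(loops) != 2:
        raise ValueError(f"shell surface must have 2 boundary loops, found {len(loops)}")
    equator, onh = loops[0], loops[-1]
    f = solve_harmonic(surface, loop_constraints(surface), validate=False)
    g = gradient(surface, f)
    if seeds is None:
        seeds = sample_seeds(equator, N)
    else:
        phase = match_inner_phase(seeds, equator)
        seeds = sample_seeds(equator, N, phase=phase)
    levels = 1.0 - np.arange(M) / (M - 1)
    lines = [
        trace_streamline(surface, f, g, seed, onh_loop=onh, seed_arclength=0.0)
        for seed in seeds
    ]
    grid = build_surface_grid(lines, levels, equator, onh)
    return grid, f, levels


def generate_shell_mesh(
    outer: TriSurface,
    inner: TriSurface,
    N: int = 40,
    M: int = 34,
    n_layers: int = 2,
    order: int = 20,
) -> MeshedShell:
    """Run the full harmonic meshing pipeline on a two-surface shell.

    Solves a harmonic field on each surface, traces N streamlines from the
    equator ring, slices M evenly spaced isolevels, assembles the
    ``N*(M-1)*n_layers``-element hexahedral shell and (for ``order=20``)
    upgrades to serendipity elements with surface-projected mid-edge nodes.
    Inner seeds are phase-aligned to the outer seeds so the two grids share
    topology.
    """
    if order not in (8, 20):
        raise ValueError("order must be 8 or 20")
    grid_o, f_o, levels = _surface_grid(outer, N, M)
    grid_i, f_i, _ = _surface_grid(inner, N, M, seeds=grid_o.nodes[:, 0])
    mesh = assemble_hex_mesh(grid_o, grid_i, n_layers=n_layers)
    if order == 20:
        mesh = convert_to_20node(mesh, outer, inner)
    return MeshedShell(mesh, outer, inner, f_o, f_i, grid_o, grid_i, levels)
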