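"""Gradient streamlines and isocontours of a harmonic surface field.

Streamlines are integral curves of the negative field gradient, traced from
evenly spaced seeds on the equator ring down to the ONH canal ring.  Because
the field is piecewise linear, its gradient is constant inside each triangle
and every streamline is an exact polyline: a straight segment inside each
triangle joined at exact edge crossings — no numerical ODE integration and
no step-size tuning.  Isocontours at evenly spaced field values are closed
rings extracted by marching over triangles.  The two families are mutually
near-orthogonal and together form a structured quad grid on the surface
whose nodes lie exactly on the input triangulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_io import BoundaryLoop, TriSurface

__all__ = [
    "Streamline",
    "IsoContour",
    "StructuredQuadGrid",
    "sample_seeds",
    "seed_to_triangle",
    "trace_streamline",
    "extract_isocontours",
    "build_surface_grid",
    "match_inner_phase",
]

MAX_SEEDS = 2048  # resolution cap for seed sampling
_TIE_EPS = 1e-12  # deterministic perturbation for vertex hits


class TracingError(RuntimeError):
    pass


@dataclass
class Streamline:
    """Exact polyline following -grad f from an equator seed toward the ONH."""

    triangles: np.ndarray  # (k,) triangle id per sample
    bary: np.ndarray  # (k, 3) barycentric coordinates
    points: np.ndarray  # (k, 3)
    values: np.ndarray  # (k,) field values, strictly decreasing
    seed_arclength: float = 0.0
    reached_onh: bool = False

    def point_at_level(self, level: float) -> np.ndarray:
        """Unique point with f = level, by monotone interpolation along samples."""
        f = self.values
        if not (f[-1] <= level <= f[0]):
            raise TracingError(f"level {level} outside streamline range [{f[-1]}, {f[0]}]")
        k = int(np.searchsorted(-f, -level, side="left"))
        if k == 0:
            return self.points[0].copy()
        f0, f1 = f[k - 1], f[k]
        t = 0.0 if f0 == f1 else (f0 - level) / (f0 - f1)
        return (1 - t) * self.points[k - 1] + t * self.points[k]


@dataclass
class IsoContour:
    """Closed on-surface polyline at a fixed field value."""

    level: float
    points: np.ndarray  # (k, 3), closed (last connects to first)
    triangles: np.ndarray  # (k,) triangle carrying each segment start

    @property
    def length(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


@dataclass
class StructuredQuadGrid:
    """N (circumferential, periodic) x M (meridional) on-surface node array.

    ``nodes[i, j]`` is the point on streamline i at ``levels[j]``; row 0 lies
    on the equator loop and row M-1 on the ONH loop.
    """

    nodes: np.ndarray  # (N, M, 3)
    levels: np.ndarray  # (M,) descending field values

    @property
    def N(self) -> int:
        return self.nodes.shape[0]

    @property
    def M(self) -> int:
        return self.nodes.shape[1]


def sample_seeds(loop: BoundaryLoop, N: int, phase: float = 0.0) -> np.ndarray:
    """N points at equal arc-length spacing around a loop, starting at ``phase``."""
    if N < 3:
        raise ValueError("need at least 3 seeds")
    if N > MAX_SEEDS:
        raise ValueError(f"seed count exceeds cap {MAX_SEEDS}")
    s = phase + loop.total_length * np.arange(N) / N
    return np.atleast_2d(loop.point_at(s))


def _bary_gradients(surface: TriSurface, tri: int) -> tuple[np.ndarray, np.ndarray]:
    """(3,3) gradients of the barycentric coordinates of one triangle, and its corners."""
    p = surface.vertices[surface.triangles[tri]]
    nrm = np.cross(p[1] - p[0], p[2] - p[0])
    a2 = np.linalg.norm(nrm)
    nhat = nrm / a2
    g = np.stack(
        [
            np.cross(nhat, p[2] - p[1]),
            np.cross(nhat, p[0] - p[2]),
            np.cross(nhat, p[1] - p[0]),
        ]
    ) / a2
    return g, p


def seed_to_triangle(surface: TriSurface, seed: np.ndarray) -> tuple[int, np.ndarray]:
    """Locate a seed lying on a boundary edge: (triangle id, barycentric)."""
    bmask = surface.boundary_edge_mask
    bedges = surface.edges[bmask]
    btris = surface._edge_tris[bmask][:, 0]
    v = surface.vertices
    a, b = v[bedges[:, 0]], v[bedges[:, 1]]
    ab = b - a
    denom = np.maximum(np.sum(ab * ab, axis=1), 1e-300)
    t = np.clip(np.sum((seed - a) * ab, axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d = np.linalg.norm(proj - seed, axis=1)
    k = int(np.argmin(d))
    tri = int(btris[k])
    corners = surface.triangles[tri]
    lam = np.zeros(3)
    for loc in range(3):
        if corners[loc] == bedges[k, 0]:
            lam[loc] = 1.0 - t[k]
        elif corners[loc] == bedges[k, 1]:
            lam[loc] = t[k]
    # nudge off the edge so the first step starts strictly inside
    lam = np.clip(lam, _TIE_EPS, None)
    lam /= lam.sum()
    return tri, lam


def trace_streamline(
    surface: TriSurface,
    f: np.ndarray,
    grad: np.ndarray,
    seed: np.ndarray,
    onh_loop: BoundaryLoop | None = None,
    stop_level: float = 1e-3,
    seed_arclength: float = 0.0,
    max_steps: int | None = None,
) -> Streamline:
    """Trace one descending streamline from an equator seed.

    Follows -grad f exactly: a straight segment inside each triangle, then a
    barycentric transfer across the exit edge.  Terminates when f drops to
    ``stop_level`` or a boundary is hit; the final point is then snapped onto
    the ONH loop so the streamline "converges" onto the canal ring exactly.
    """
    neighbors = _triangle_neighbors(surface)
    tri, lam = seed_to_triangle(surface, seed)
    fvals = f[surface.triangles]
    max_steps = max_steps or 40 * len(surface.triangles)
    tris_out, bary_out, pts_out, f_out = [], [], [], []
    visits: dict[int, int] = {}

    def record(tri_id, lam_):
        p = lam_ @ surface.vertices[surface.triangles[tri_id]]
        val = float(lam_ @ fvals[tri_id])
        tris_out.append(tri_id)
        bary_out.append(lam_.copy())
        pts_out.append(p)
        f_out.append(val)
        return p, val

    record(tri, lam)
    pts_out[0] = np.asarray(seed, dtype=float).copy()  # exact on-loop start
    reached = False
    _LAM_TOL = 1e-6  # barycentric scale below which motion counts as edge-pinned
    tris = surface.triangles

    def transfer(src: int, dst: int, lam_src: np.ndarray) -> np.ndarray:
        """Re-express an on-shared-edge point in the neighbour's barycentrics."""
        cur = tris[src]
        nxt = tris[dst]
        lam_dst = np.zeros(3)
        for loc in range(3):
            hit = np.nonzero(cur == nxt[loc])[0]
            if hit.size:
                lam_dst[loc] = lam_src[hit[0]]
        lam_dst = np.clip(lam_dst, _TIE_EPS, None)
        return lam_dst / lam_dst.sum()

    def descent_dir(tri_id: int) -> np.ndarray:
        g = grad[tri_id]
        gn = np.linalg.norm(g)
        if gn < 1e-12:
            raise TracingError(f"stagnation: zero gradient in triangle {tri_id}")
        bgrad, _ = _bary_gradients(surface, tri_id)
        return bgrad @ (-g / gn)

    for _ in range(max_steps):
        visits[tri] = visits.get(tri, 0) + 1
        if visits[tri] > 24:
            raise TracingError(f"cycling detected at triangle {tri}")
        dlam = descent_dir(tri)

        def exit_time(d):
            with np.errstate(divide="ignore"):
                return np.where(d < -1e-300, -lam / np.minimum(d, -1e-300), np.inf)

        t_cand = exit_time(dlam)
        k_exit = int(np.argmin(t_cand))
        t_exit = float(t_cand[k_exit])
        scale = np.abs(dlam).max()
        boundary_stop = False
        if t_exit * scale < _LAM_TOL:
            # On an edge or vertex with the exit blocked at zero distance.
            # First try a consistent crossing: a zeroed edge through which
            # the descent leaves AND whose neighbour carries it onward into
            # its own interior.  Failing that the flow is genuinely pinned to
            # the edge: slide along it toward decreasing f, or hop around the
            # vertex fan when even the slide direction vanishes.
            on_zero = lam <= _LAM_TOL
            hopped = False
            for i in np.argsort(dlam):
                if not (on_zero[i] and dlam[i] < 0):
                    continue
                nb = int(neighbors[tri, i])
                if nb < 0:
                    continue
                lam_try = lam.copy()
                lam_try[i] = 0.0
                lam_nb = transfer(tri, nb, lam_try)
                # coordinate of the neighbour vertex opposite the shared edge
                j = int(np.nonzero(~np.isin(tris[nb], tris[tri]))[0][0])
                d_nb = descent_dir(nb)
                if d_nb[j] > 1e-9 * max(np.abs(d_nb).max(), 1.0):
                    tri, lam = nb, lam_nb
                    hopped = True
                    break
            if hopped:
                continue
            d = dlam.copy()
            clamp = on_zero & (d < 0)
            if clamp.any():
                excess = d[clamp].sum()
                d[clamp] = 0.0
                active = ~clamp
                d[active] += excess / active.sum()
            if np.abs(d).max() < 1e-9 * max(scale, 1.0):
                # vertex fan: hop across the steepest zeroed descending edge
                blocked = np.where(on_zero, dlam, np.inf)
                k_exit = int(np.argmin(blocked))
                if not (blocked[k_exit] < 0):
                    raise TracingError(f"stagnation on edge of triangle {tri}")
                t_exit = 0.0
                dlam = np.zeros(3)
            else:
                dlam = d
                t_cand = exit_time(dlam)
                k_exit = int(np.argmin(t_cand))
                t_exit = float(t_cand[k_exit])
        if not np.isfinite(t_exit):
            raise TracingError(f"no exit direction in triangle {tri}")
        lam_new = lam + t_exit * dlam
        lam_new[k_exit] = 0.0
        lam_new = np.clip(lam_new, 0.0, None)
        lam_new /= lam_new.sum()
        _, val = record(tri, lam_new)
        if val <= stop_level:
            reached = True
            break
        nb = int(neighbors[tri, k_exit])
        if nb < 0:
            # hit a boundary edge before the stop level: acceptable only on
            # the low-f (ONH) side of the field
            reached = val <= max(10 * stop_level, 0.1)
            break
        tri, lam = nb, transfer(tri, nb, lam_new)
    else:
        raise TracingError("step cap exceeded while tracing streamline")

    sl = Streamline(
        np.array(tris_out, dtype=np.intp),
        np.array(bary_out),
        np.array(pts_out),
        np.array(f_out),
        seed_arclength=seed_arclength,
        reached_onh=reached,
    )
    if onh_loop is not None:
        # snap the terminal point precisely onto the canal ring
        end = sl.points[-1]
        snapped = _closest_on_loop(onh_loop, end)
        sl.points = np.vstack([sl.points, snapped])
        sl.values = np.concatenate([sl.values, [min(sl.values[-1], 0.0)]])
        sl.triangles = np.concatenate([sl.triangles, sl.triangles[-1:]])
        sl.bary = np.vstack([sl.bary, sl.bary[-1:]])
        sl.reached_onh = True
    return sl


def _closest_on_loop(loop: BoundaryLoop, p: np.ndarray) -> np.ndarray:
    pts = loop.points
    nxt = np.roll(pts, -1, axis=0)
    ab = nxt - pts
    denom = np.maximum(np.sum(ab * ab, axis=1), 1e-300)
    t = np.clip(np.sum((p - pts) * ab, axis=1) / denom, 0.0, 1.0)
    proj = pts + t[:, None] * ab
    d = np.linalg.norm(proj - p, axis=1)
    return proj[int(np.argmin(d))]


_NEIGHBOR_CACHE: dict[int, np.ndarray] = {}


def _triangle_neighbors(surface: TriSurface) -> np.ndarray:
    """Neighbour across the edge opposite each local vertex (or -1)."""
    key = id(surface)
    if key not in _NEIGHBOR_CACHE:
        t = surface.triangles
        m = len(t)
        out = np.full((m, 3), -1, dtype=np.intp)
        # edge opposite local vertex k is (k+1, k+2)
        for k in range(3):
            a = t[:, (k + 1) % 3]
            b = t[:, (k + 2) % 3]
            und = np.sort(np.stack([a, b], axis=1), axis=1)
            # locate edge ids by searching the surface edge table
            eidx = _edge_lookup(surface, und)
            pair = surface._edge_tris[eidx]
            own = np.arange(m)
            out[:, k] = np.where(pair[:, 0] == own, pair[:, 1], pair[:, 0])
        _NEIGHBOR_CACHE[key] = out
        if len(_NEIGHBOR_CACHE) > 16:
            _NEIGHBOR_CACHE.pop(next(iter(_NEIGHBOR_CACHE)))
    return _NEIGHBOR_CACHE[key]


def _edge_lookup(surface: TriSurface, und: np.ndarray) -> np.ndarray:
    e = surface.edges
    # lexicographic binary search over the sorted unique edge table
    keys = e[:, 0].astype(np.int64) * (surface.vertices.shape[0] + 1) + e[:, 1]
    order = np.argsort(keys)
    q = und[:, 0].astype(np.int64) * (surface.vertices.shape[0] + 1) + und[:, 1]
    pos = np.searchsorted(keys[order], q)
    return order[pos]


def extract_isocontours(
    surface: TriSurface,
    f: np.ndarray,
    levels,
    grad: np.ndarray | None = None,
    expect_single: bool = True,
) -> list[IsoContour]:
    """Closed isocontours by marching over triangles with linear interpolation.

    Each contour is oriented along g x n (gradient cross outward normal), the
    circumferential direction used for the material x-axis, which matches the
    equator-loop winding on a sclera shell.  Vertex-value ties are broken by
    nudging the vertex value by 1e-12, deterministically.
    """
    from .harmonic_field import gradient as _gradient

    if grad is None:
        grad = _gradient(surface, f)
    t = surface.triangles
    v = surface.vertices
    normals = surface.triangle_normals
    out = []
    for level in np.atleast_1d(levels):
        fv = f.copy()
        tie = fv == level
        fv[tie] = level + _TIE_EPS
        ft = fv[t]
        lo = ft.min(axis=1) < level
        hi = ft.max(axis=1) > level
        crossing = np.nonzero(lo & hi)[0]
        if crossing.size == 0:
            raise TracingError(f"no contour at level {level}")
        # for each crossing triangle, the two crossed edges and their points
        seg_edges: dict[int, list[tuple[int, int]]] = {}
        edge_pts: dict[tuple[int, int], np.ndarray] = {}
        for tri in crossing:
            ids = t[tri]
            vals = fv[ids]
            crossed = []
            for k in range(3):
                a, b = ids[k], ids[(k + 1) % 3]
                fa, fb = fv[a], fv[b]
                if (fa - level) * (fb - level) < 0:
                    key = (min(a, b), max(a, b))
                    w = (fa - level) / (fa - fb)
                    edge_pts[key] = (1 - w) * v[a] + w * v[b]
                    crossed.append(key)
            if len(crossed) == 2:
                seg_edges[tri] = crossed
        # chain segments into closed polylines via shared crossed edges
        edge_to_tris: dict[tuple[int, int], list[int]] = {}
        for tri, (ea, eb) in seg_edges.items():
            edge_to_tris.setdefault(ea, []).append(tri)
            edge_to_tris.setdefault(eb, []).append(tri)
        unvisited = set(seg_edges)
        components = []
        while unvisited:
            start = next(iter(unvisited))
            comp_pts = []
            comp_tris = []
            tri = start
            enter = seg_edges[tri][0]
            while True:
                unvisited.discard(tri)
                ea, eb = seg_edges[tri]
                exit_e = eb if enter == ea else ea
                comp_pts.append(edge_pts[enter])
                comp_tris.append(tri)
                nbs = [x for x in edge_to_tris.get(exit_e, []) if x != tri]
                if not nbs:
                    # open chain (touches boundary) — walk back not supported
                    break
                tri = nbs[0]
                enter = exit_e
                if tri == start:
                    break
            components.append((np.array(comp_pts), np.array(comp_tris, dtype=np.intp)))
        if expect_single and len(components) != 1:
            raise TracingError(
                f"level {level} produced {len(components)} components (annular topology expected 1)"
            )
        components.sort(key=lambda c: -len(c[0]))
        pts, ctris = components[0]
        # orient along g x n at the first segment
        ref = np.cross(grad[ctris[0]], normals[ctris[0]])
        tangent = pts[1] - pts[0]
        if np.dot(tangent, ref) < 0:
            pts = pts[::-1].copy()
            ctris = ctris[::-1].copy()
        out.append(IsoContour(float(level), pts, ctris))
    return out


def build_surface_grid(
    streamlines: list[Streamline],
    levels: np.ndarray,
    equator_loop: BoundaryLoop,
    onh_loop: BoundaryLoop,
) -> StructuredQuadGrid:
    """Assemble the N x M structured grid from N streamlines and M levels.

    ``levels`` must be sorted descending with levels[0] = equator value and
    levels[-1] = ONH value; boundary rows reuse the streamlines' on-loop end
    points so the grid boundary lies exactly on the input boundary rings.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(np.diff(levels) >= 0):
        raise ValueError("levels must be strictly descending (equator side first)")
    N = len(streamlines)
    M = len(levels)
    nodes = np.empty((N, M, 3))
    for i, sl in enumerate(streamlines):
        if not sl.reached_onh:
            raise TracingError(f"streamline {i} terminated before the ONH ring")
        nodes[i, 0] = sl.points[0]
        nodes[i, M - 1] = sl.points[-1]
        for j in range(1, M - 1):
            nodes[i, j] = sl.point_at_level(levels[j])
    return StructuredQuadGrid(nodes, levels)


def match_inner_phase(
    outer_seeds: np.ndarray, inner_loop: BoundaryLoop, n_candidates: int = 1024
) -> float:
    """Seed phase on the inner equator ring minimizing distance to outer seeds.

    The outer and inner surface grids must share topology; this aligns their
    circumferential parameterizations by brute-force search over the phase,
    refined by local parabolic steps.
    """
    N = len(outer_seeds)
    L = inner_loop.total_length

    def cost(p: float) -> float:
        s = p + L * np.arange(N) / N
        pts = inner_loop.point_at(s)
        return float(np.sum((pts - outer_seeds) ** 2))

    cand = np.linspace(0, L, n_candidates, endpoint=False)
    costs = [cost(p) for p in cand]
    best = int(np.argmin(costs))
    # local refinement around the best candidate
    lo = cand[best] - L / n_candidates
    hi = cand[best] + L / n_candidates
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(cost, bounds=(lo, hi), method="bounded")
    return float(res.x if res.fun <= costs[best] else cand[best])
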