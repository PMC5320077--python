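"""Synthetic sclera-like shell fixtures and analytic test geometries.

No scleral scan ships with the package, so every downstream stage is
exercised on generated geometry.  :func:`make_sclera_fixture` emulates the
posterior scleral shell: a hemisphere of outer radius ``R_out`` with a
circular optic-nerve-head (ONH) canal hole offset from the posterior pole,
and a wall thickness tapering smoothly from 1.1 mm at the pole to 0.38 mm at
the equator (the roughly 3:1 regional variation seen in human sclera).

Also provided: a flat annulus (the harmonic field on it has the closed-form
log-radial solution) and a mapped hexahedral octant of a thick spherical
shell (the Lamé pressure-vessel benchmark for the FE solver).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh_io import HexMesh, TriSurface, closest_point_on_surface

__all__ = [
    "ScleraFixtureSpec",
    "make_sclera_fixture",
    "compute_thickness_map",
    "make_annulus_fixture",
    "make_cylinder_fixture",
    "make_mapped_spherical_shell",
    "thickness_profile",
]


@dataclass
class ScleraFixtureSpec:
    """Parameters of the synthetic posterior-sclera shell.

    All lengths in mm, angles in degrees.  ``n_circ`` and ``n_merid`` are the
    circumferential and meridional vertex counts of the structured surface
    triangulation.
    """

    R_out: float = 12.0
    r_canal: float = 1.75
    canal_offset_deg: float = 15.0
    t_pole: float = 1.1
    t_eq: float = 0.38
    n_circ: int = 96
    n_merid: int = 48
    jitter: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.t_eq <= self.t_pole < self.R_out):
            raise ValueError("need 0 < t_eq <= t_pole < R_out")
        if self.n_circ < 8 or self.n_merid < 8:
            raise ValueError("angular resolutions must be >= 8")
        canal_arc_deg = np.degrees(self.r_canal / self.R_out)
        if self.canal_offset_deg + canal_arc_deg >= 85.0:
            raise ValueError("canal must lie strictly inside the hemisphere")
        if self.r_canal <= 0:
            raise ValueError("canal radius must be positive")


def thickness_profile(theta: np.ndarray, spec: ScleraFixtureSpec) -> np.ndarray:
    """Shell thickness (mm) at polar angle ``theta`` (radians from the pole).

    Cosine-squared blend between the pole and equator values: smooth,
    monotone, with zero slope at both ends.
    """
    theta = np.asarray(theta, dtype=float)
    return spec.t_eq + (spec.t_pole - spec.t_eq) * np.cos(theta) ** 2


def _slerp(a: np.ndarray, b: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Great-circle interpolation between unit vectors a, b (broadcast over t)."""
    dot = np.clip(np.sum(a * b, axis=-1, keepdims=True), -1.0, 1.0)
    omega = np.arccos(dot)
    so = np.sin(omega)
    small = so < 1e-12
    w0 = np.where(small, 1 - t, np.sin((1 - t) * omega) / np.where(small, 1, so))
    w1 = np.where(small, t, np.sin(t * omega) / np.where(small, 1, so))
    return w0 * a + w1 * b


def _structured_tri_grid(n_circ: int, n_merid: int) -> np.ndarray:
    """Triangulate an (n_merid+1) x n_circ vertex grid, periodic in the circ index.

    Vertex (j, i) has index j * n_circ + i. Rows j=0 (canal rim) and
    j=n_merid (equator) become the two boundary loops.
    """
    tris = []
    for j in range(n_merid):
        for i in range(n_circ):
            i1 = (i + 1) % n_circ
            a = j * n_circ + i
            b = j * n_circ + i1
            c = (j + 1) * n_circ + i1
            d = (j + 1) * n_circ + i
            # split each quad along a consistent diagonal
            tris.append((a, b, c))
            tris.append((a, c, d))
    return np.array(tris, dtype=np.intp)


def make_sclera_fixture(spec: ScleraFixtureSpec | None = None) -> tuple[TriSurface, TriSurface]:
    """Generate the (outer, inner) posterior-sclera shell surfaces.

    The outer surface lies exactly on the sphere of radius ``R_out``; the
    pole is at (0, 0, -R_out) and the equator ring in the z = 0 plane.  The
    canal rim is a geodesic circle of radius ``r_canal`` whose centre is
    tilted ``canal_offset_deg`` from the pole (toward +x).  Meridional grid
    lines run from the canal rim to the equator along great circles, so the
    surface has exactly two boundary loops.  The inner surface offsets every
    outer vertex radially inward by the thickness profile.  Optional seeded
    jitter perturbs interior vertices tangentially to break the rotational
    symmetry.
    """
    spec = spec or ScleraFixtureSpec()
    spec.validate()
    R = spec.R_out
    alpha_c = spec.r_canal / R  # angular radius of the canal (geodesic)
    off = np.radians(spec.canal_offset_deg)
    # canal axis, tilted from the pole (-z) toward +x
    c_axis = np.array([np.sin(off) * 1.0, 0.0, -np.cos(off)])
    # orthonormal frame around the canal axis
    e1 = np.array([np.cos(off), 0.0, np.sin(off)])
    e2 = np.array([0.0, 1.0, 0.0])

    phis = 2 * np.pi * np.arange(spec.n_circ) / spec.n_circ
    # canal-rim directions (unit): rotate the axis by alpha_c toward azimuth phi
    rim = (
        np.cos(alpha_c) * c_axis[None, :]
        + np.sin(alpha_c) * (np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2)
    )
    # equator-ring directions at matching azimuths
    eq = np.stack([np.cos(phis), np.sin(phis), np.zeros_like(phis)], axis=1)

    ts = np.linspace(0.0, 1.0, spec.n_merid + 1)
    dirs = np.empty((spec.n_merid + 1, spec.n_circ, 3))
    for j, t in enumerate(ts):
        dirs[j] = _slerp(rim, eq, t)
    dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        # tangential perturbation of interior rows only (boundaries stay exact)
        pert = rng.normal(scale=spec.jitter / R, size=dirs.shape)
        pert[0] = 0.0
        pert[-1] = 0.0
        pert -= np.sum(pert * dirs, axis=-1, keepdims=True) * dirs
        dirs = dirs + pert
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)

    verts_outer = (R * dirs).reshape(-1, 3)
    theta = np.arccos(np.clip(-dirs[..., 2], -1.0, 1.0))  # polar angle from pole
    t_field = thickness_profile(theta, spec)
    verts_inner = ((R - t_field)[..., None] * dirs).reshape(-1, 3)

    tris = _structured_tri_grid(spec.n_circ, spec.n_merid)
    outer = TriSurface(verts_outer, tris.copy())
    inner = TriSurface(verts_inner, tris.copy())
    return outer, inner


def compute_thickness_map(outer: TriSurface, inner: TriSurface) -> np.ndarray:
    """Per-outer-vertex shell thickness: distance to the closest inner-surface point.

    Exact point-to-triangle distances (not point-to-vertex). Raises if any
    distance exceeds half the outer bounding radius, which signals that the
    two surfaces do not form a shell.
    """
    _, dist, _ = closest_point_on_surface(inner, outer.vertices)
    r_scale = np.linalg.norm(outer.vertices, axis=1).max()
    if np.any(dist > 0.5 * r_scale):
        raise ValueError("surfaces do not form a shell (closest point too far)")
    if np.any(dist <= 0):
        raise ValueError("thickness must be strictly positive")
    return dist


def make_annulus_fixture(r_in: float, r_out: float, resolution: int = 48) -> TriSurface:
    """Flat annulus in the z = 0 plane with two boundary loops.

    ``resolution`` is the circumferential vertex count; the radial count is
    scaled to keep triangles roughly isotropic.
    """
    if not (0 < r_in < r_out):
        raise ValueError("need 0 < r_in < r_out")
    n_circ = int(resolution)
    n_rad = max(2, int(round(resolution * (r_out - r_in) / (np.pi * (r_in + r_out)))))
    radii = np.linspace(r_in, r_out, n_rad + 1)
    phis = 2 * np.pi * np.arange(n_circ) / n_circ
    rr, pp = np.meshgrid(radii, phis, indexing="ij")
    verts = np.stack([rr * np.cos(pp), rr * np.sin(pp), np.zeros_like(rr)], axis=-1)
    tris = _structured_tri_grid(n_circ, n_rad)
    return TriSurface(verts.reshape(-1, 3), tris)


def make_cylinder_fixture(radius: float, height: float, n_circ: int = 48, n_axial: int = 24) -> TriSurface:
    """Open right circular cylinder side wall (boundaries at z = 0 and z = height).

    The axial grid lines make the linear-in-height field the exact discrete
    harmonic solution, a sharp oracle for the field solver and the tracer.
    """
    zs = np.linspace(0.0, height, n_axial + 1)
    phis = 2 * np.pi * np.arange(n_circ) / n_circ
    zz, pp = np.meshgrid(zs, phis, indexing="ij")
    verts = np.stack([radius * np.cos(pp), radius * np.sin(pp), zz], axis=-1)
    tris = _structured_tri_grid(n_circ, n_axial)
    return TriSurface(verts.reshape(-1, 3), tris)


def make_mapped_spherical_shell(
    r_in: float, r_out: float, n_angular: int = 4, n_radial: int = 2
) -> HexMesh:
    """Mapped hexahedral mesh of one octant of a thick spherical shell.

    The spherical octant (the +x, +y, +z triangle with three 90° corners) is
    covered by three quad patches: corners -> edge midpoints -> face centre,
    each meshed ``n_angular`` x ``n_angular`` and swept through ``n_radial``
    radial divisions, giving ``3 * n_angular**2 * n_radial`` hexahedra.
    Named sets: face sets ``inner``/``outer`` (spherical walls) and node sets
    ``sym_x``/``sym_y``/``sym_z`` (coordinate symmetry planes).
    """
    if not (0 < r_in < r_out):
        raise ValueError("need 0 < r_in < r_out")
    if n_angular < 1 or n_radial < 1:
        raise ValueError("divisions must be >= 1")
    A = np.array([1.0, 0.0, 0.0])
    B = np.array([0.0, 1.0, 0.0])
    C = np.array([0.0, 0.0, 1.0])

    def unit(v):
        return v / np.linalg.norm(v, axis=-1, keepdims=True)

    Mab, Mbc, Mca = unit(A + B), unit(B + C), unit(C + A)
    G = unit(A + B + C)
    patches = [
        (A, Mab, G, Mca),
        (B, Mbc, G, Mab),
        (C, Mca, G, Mbc),
    ]
    n = n_angular
    us = np.linspace(0, 1, n + 1)
    radii = np.linspace(r_in, r_out, n_radial + 1)
    node_map: dict[tuple, int] = {}
    nodes: list[np.ndarray] = []

    def node_id(p: np.ndarray) -> int:
        key = tuple(np.round(p, 9))
        if key not in node_map:
            node_map[key] = len(nodes)
            nodes.append(p)
        return node_map[key]

    elements = []
    inner_faces = []
    outer_faces = []
    for P0, P1, P2, P3 in patches:
        # bilinear blend in parameter space, projected to the unit sphere
        uu, vv = np.meshgrid(us, us, indexing="ij")
        pts = (
            (1 - uu)[..., None] * (1 - vv)[..., None] * P0
            + uu[..., None] * (1 - vv)[..., None] * P1
            + (uu * vv)[..., None] * P2
            + (1 - uu)[..., None] * vv[..., None] * P3
        )
        pts = unit(pts)
        for i in range(n):
            for j in range(n):
                quad_dirs = [pts[i, j], pts[i + 1, j], pts[i + 1, j + 1], pts[i, j + 1]]
                for k in range(n_radial):
                    r0, r1 = radii[k], radii[k + 1]
                    bottom = [node_id(r0 * d) for d in quad_dirs]
                    top = [node_id(r1 * d) for d in quad_dirs]
                    eidx = len(elements)
                    elements.append(bottom + top)
                    if k == 0:
                        inner_faces.append((eidx, 4))  # zeta=-1 face
                    if k == n_radial - 1:
                        outer_faces.append((eidx, 5))  # zeta=+1 face
    nodes_arr = np.array(nodes)
    elems_arr = np.array(elements, dtype=np.intp)
    # fix handedness: radial sweep outward must give positive Jacobians
    from .hex_mesher import scaled_jacobians  # local import to avoid cycle

    sj = scaled_jacobians(HexMesh(nodes_arr, elems_arr))
    if np.median(sj) < 0:
        elems_arr = elems_arr[:, [4, 5, 6, 7, 0, 1, 2, 3]]
        inner_faces = [(e, 5) for e, _ in inner_faces]
        outer_faces = [(e, 4) for e, _ in outer_faces]
    tol = 1e-9
    node_sets = {
        "sym_x": np.nonzero(np.abs(nodes_arr[:, 0]) < tol)[0],
        "sym_y": np.nonzero(np.abs(nodes_arr[:, 1]) < tol)[0],
        "sym_z": np.nonzero(np.abs(nodes_arr[:, 2]) < tol)[0],
    }
    face_sets = {
        "inner": np.array(inner_faces, dtype=np.intp),
        "outer": np.array(outer_faces, dtype=np.intp),
    }
    return HexMesh(nodes_arr, elems_arr, node_sets=node_sets, face_sets=face_sets)
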