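"""Per-element material frames, scleral region labels and elastic constants.

Scleral collagen runs mostly circumferentially around the optic nerve head,
so each element receives a local orthonormal frame derived from the same
harmonic field that drove the meshing: the y-axis follows the surface
gradient (meridional fibres), the z-axis the outward thickness direction,
and the x-axis their cross product — the circumferential fibre direction
tangent to the field's isocontours.

The fibre-rotation comparison models r1..r10 tilt the in-plane axes about z
region by region: model rk rotates the peripapillary band by (k-1)*10
degrees and the peripheral band by k*10 degrees (r0 is the perfect
circumferential model).  Orthotropic constants default to the scleral set
E_x = 8.6, E_y = 6, E_z = 2.5 MPa with nu = 0.49; the isotropic comparison
model uses E = 3.8 MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .harmonic_field import gradient as field_gradient
from .mesh_io import HexMesh, TriSurface, closest_point_on_surface

__all__ = [
    "Region",
    "FiberRotationScheme",
    "OrthotropicMaterial",
    "IsotropicMaterial",
    "SCLERA_ORTHOTROPIC",
    "SCLERA_ISOTROPIC",
    "assign_local_frames",
    "label_regions",
    "apply_rotation_scheme",
    "build_stiffness",
    "build_stiffness_batch",
    "rotate_stiffness",
]


class Region(IntEnum):
    ONH_ADJACENT = 0
    PERIPAPILLARY = 1
    PERIPHERAL = 2


@dataclass(frozen=True)
class FiberRotationScheme:
    """Region-wise in-plane fibre rotation, scheme id k in 0..10.

    k = 0 is the perfect circumferential model; for k >= 1 the peripapillary
    band (and the ONH-adjacent band with it) rotates by (k-1)*10 degrees and
    the peripheral band by k*10 degrees, both capped at the quarter turn that
    swaps the fibre families: r10 is (80, 90) degrees.  The cap is the only
    rule consistent with every printed model (r1 peripheral 10; r2 10/20;
    r3 20/30; r10 80/90) and keeps all angles within [0, 90] degrees.
    """

    k: int

    def __post_init__(self):
        if not (0 <= self.k <= 10):
            raise ValueError("scheme id must be in 0..10")

    @property
    def peripapillary_deg(self) -> float:
        return 0.0 if self.k == 0 else min((self.k - 1) * 10.0, 80.0)

    @property
    def peripheral_deg(self) -> float:
        return min(self.k * 10.0, 90.0)

    def angle_for(self, region: int) -> float:
        if region == Region.PERIPHERAL:
            return self.peripheral_deg
        return self.peripapillary_deg  # ONH-adjacent rotates with peripapillary


_VOIGT_PAIRS = [(0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1)]


def _voigt_to_tensor(C: np.ndarray) -> np.ndarray:
    T = np.zeros((3, 3, 3, 3))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            T[i, j, k, l] = T[j, i, k, l] = T[i, j, l, k] = T[j, i, l, k] = C[a, b]
    return T


def _tensor_to_voigt(T: np.ndarray) -> np.ndarray:
    C = np.empty(T.shape[:-4] + (6, 6))
    for a, (i, j) in enumerate(_VOIGT_PAIRS):
        for b, (k, l) in enumerate(_VOIGT_PAIRS):
            C[..., a, b] = T[..., i, j, k, l]
    return C


@dataclass(frozen=True)
class OrthotropicMaterial:
    """Orthotropic linear elasticity in the local fibre frame (MPa).

    A single Poisson ratio is applied as nu_xy = nu_yz = nu_xz, with the
    reciprocal ratios from symmetry of the compliance (nu_ji = nu_ij E_j /
    E_i).  Shear moduli are not independently specified for sclera; the
    closure G_ij = sqrt(E_i E_j) / (2 (1 + nu)) is used, which reduces to
    the exact isotropic shear modulus when the three moduli coincide.
    Stiffness positive definiteness is verified at construction.
    """

    E_x: float = 8.6
    E_y: float = 6.0
    E_z: float = 2.5
    nu: float = 0.49
    shear_moduli: tuple | None = None  # optional override (G_yz, G_xz, G_xy)

    def __post_init__(self):
        if min(self.E_x, self.E_y, self.E_z) <= 0:
            raise ValueError("elastic moduli must be positive")
        self.stiffness_local()  # raises if not SPD

    def compliance_local(self) -> np.ndarray:
        Ex, Ey, Ez, nu = self.E_x, self.E_y, self.E_z, self.nu
        if self.shear_moduli is not None:
            Gyz, Gxz, Gxy = self.shear_moduli
        else:
            Gyz = np.sqrt(Ey * Ez) / (2 * (1 + nu))
            Gxz = np.sqrt(Ex * Ez) / (2 * (1 + nu))
            Gxy = np.sqrt(Ex * Ey) / (2 * (1 + nu))
        S = np.zeros((6, 6))
        S[0, 0], S[1, 1], S[2, 2] = 1 / Ex, 1 / Ey, 1 / Ez
        S[0, 1] = S[1, 0] = -nu / Ex  # nu_xy / E_x = nu_yx / E_y
        S[0, 2] = S[2, 0] = -nu / Ex
        S[1, 2] = S[2, 1] = -nu / Ey
        S[3, 3], S[4, 4], S[5, 5] = 1 / Gyz, 1 / Gxz, 1 / Gxy
        return S

    def stiffness_local(self) -> np.ndarray:
        S = self.compliance_local()
        C = np.linalg.inv(S)
        ev = np.linalg.eigvalsh(0.5 * (C + C.T))
        if ev.min() <= 0:
            raise ValueError(
                f"stiffness not positive definite for constants "
                f"E=({self.E_x}, {self.E_y}, {self.E_z}), nu={self.nu}"
            )
        return 0.5 * (C + C.T)


@dataclass(frozen=True)
class IsotropicMaterial:
    """Isotropic linear elasticity: spatially averaged scleral stiffness."""

    E: float = 3.8
    nu: float = 0.49

    def __post_init__(self):
        if self.E <= 0 or not (0 < self.nu < 0.5):
            raise ValueError("need E > 0 and 0 < nu < 0.5")

    def stiffness_local(self) -> np.ndarray:
        E, nu = self.E, self.nu
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        C = np.zeros((6, 6))
        C[:3, :3] = lam
        C[np.arange(3), np.arange(3)] += 2 * mu
        C[np.arange(3, 6), np.arange(3, 6)] = mu
        return C


SCLERA_ORTHOTROPIC = OrthotropicMaterial()
SCLERA_ISOTROPIC = IsotropicMaterial()


def assign_local_frames(mesh: HexMesh, surface: TriSurface, f: np.ndarray) -> np.ndarray:
    """Per-element frames (m, 3, 3), rows (x circumferential, y meridional, z thickness).

    Each element centroid is projected onto the reference (outer) surface;
    the meridional y-axis is the normalized surface-field gradient there,
    the z-axis the surface normal signed to point from the element centroid
    toward its outer-surface projection (outward through the shell), and
    x = y cross z — tangent to the isocontours with the equator-loop winding.
    """
    grad = field_gradient(surface, f)
    centroids = mesh.nodes[mesh.elements[:, :8]].mean(axis=1)
    proj, _, tri_ids = closest_point_on_surface(surface, centroids)
    g = grad[tri_ids]
    gn = np.linalg.norm(g, axis=1, keepdims=True)
    if np.any(gn < 1e-12):
        raise ValueError("zero field gradient at an element's surface projection")
    y = g / gn
    n = surface.triangle_normals[tri_ids]
    outward = proj - centroids
    sign = np.where(np.sum(n * outward, axis=1) >= 0, 1.0, -1.0)
    z = n * sign[:, None]
    z -= np.sum(z * y, axis=1, keepdims=True) * y
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=1)


def element_field_values(mesh: HexMesh, surface: TriSurface, f: np.ndarray) -> np.ndarray:
    """Harmonic field value at each element centroid's surface projection."""
    centroids = mesh.nodes[mesh.elements[:, :8]].mean(axis=1)
    proj, _, tri_ids = closest_point_on_surface(surface, centroids)
    import trimesh.triangles as tt

    tris = surface.vertices[surface.triangles[tri_ids]]
    bary = tt.points_to_barycentric(tris, proj)
    return np.sum(bary * f[surface.triangles[tri_ids]], axis=1)


def label_regions(
    mesh: HexMesh,
    surface: TriSurface,
    f: np.ndarray,
    u1: float = 0.15,
    u2: float = 0.45,
) -> np.ndarray:
    """Partition elements into ONH-adjacent / peripapillary / peripheral bands.

    Thresholds act on the normalized field value u at the element centroid's
    surface projection: u < u1 -> ONH_ADJACENT, u < u2 -> PERIPAPILLARY,
    else PERIPHERAL.  The band boundaries are therefore isocontour rings.
    """
    if not (0 < u1 < u2 < 1):
        raise ValueError("need 0 < u1 < u2 < 1")
    u = element_field_values(mesh, surface, f)
    labels = np.full(mesh.n_elements, int(Region.PERIPHERAL), dtype=np.intp)
    labels[u < u2] = int(Region.PERIPAPILLARY)
    labels[u < u1] = int(Region.ONH_ADJACENT)
    return labels


def apply_rotation_scheme(
    frames: np.ndarray, labels: np.ndarray, scheme: FiberRotationScheme | int
) -> np.ndarray:
    """Rotate the in-plane axes about each element's z-axis by its region angle."""
    if isinstance(scheme, int):
        scheme = FiberRotationScheme(scheme)
    out = frames.copy()
    for region in Region:
        theta = np.radians(scheme.angle_for(region))
        if theta == 0.0:
            continue
        sel = labels == int(region)
        c, s = np.cos(theta), np.sin(theta)
        x, y = frames[sel, 0], frames[sel, 1]
        out[sel, 0] = c * x + s * y
        out[sel, 1] = -s * x + c * y
    return out


def rotate_stiffness(C_local: np.ndarray, frames: np.ndarray) -> np.ndarray:
    """Rotate local 6x6 stiffness to global coordinates for each frame.

    ``frames`` rows are the local axes in global coordinates, so the change
    of basis A (local -> global components) is the frame transpose; the
    fourth-order tensor rotates as C'_pqrs = A_pi A_qj A_rk A_sl C_ijkl.
    """
    single = frames.ndim == 2
    F = frames[None] if single else frames
    A = np.swapaxes(F, 1, 2)  # (m, 3, 3), columns of frame = rows of A ...
    T = _voigt_to_tensor(C_local)
    Tg = np.einsum("mpi,mqj,mrk,msl,ijkl->mpqrs", A, A, A, A, T, optimize=True)
    Cg = _tensor_to_voigt(Tg)
    return Cg[0] if single else Cg


def build_stiffness(
    material: OrthotropicMaterial | IsotropicMaterial, frame: np.ndarray | None = None
) -> np.ndarray:
    """Global-coordinate 6x6 stiffness (MPa) for one element.

    Isotropic materials are frame-invariant; orthotropic materials require a
    frame.  Voigt order (xx, yy, zz, yz, xz, xy) with engineering shears.
    """
    C = material.stiffness_local()
    if isinstance(material, IsotropicMaterial) or frame is None:
        return C
    return rotate_stiffness(C, frame)


def build_stiffness_batch(
    material: OrthotropicMaterial | IsotropicMaterial, frames: np.ndarray | None, m: int
) -> np.ndarray:
    """(m, 6, 6) per-element global stiffnesses, vectorized over elements."""
    C = material.stiffness_local()
    if isinstance(material, IsotropicMaterial) or frames is None:
        return np.broadcast_to(C, (m, 6, 6)).copy()
    return rotate_stiffness(C, frames)
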