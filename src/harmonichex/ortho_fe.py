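"""Small-strain orthotropic finite elements for hexahedral shell meshes.

Solves the linear elastostatic problem on 8- or 20-node hexahedral meshes
with per-element anisotropic stiffness (local fibre frames), fixed equator
nodes and a uniform normal pressure on the inner surface — the intraocular
pressure (IOP) load case.  20-node serendipity elements use full 3x3x3
Gauss quadrature; the 8-node path uses 2x2x2 quadrature with a mean-
dilatation (B-bar) treatment of the volumetric term, which suppresses
locking at the nearly incompressible nu = 0.49.

Displacements are in mm, stresses in MPa; pressures given in mmHg are
converted with 1 mmHg = 133.3224e-6 MPa.  Loads act on the undeformed
geometry (consistent with geometric linearity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh_io import HEX_EDGES, HexMesh
from .material_frames import (
    IsotropicMaterial,
    OrthotropicMaterial,
    Region,
    build_stiffness_batch,
)

__all__ = [
    "FEProblem",
    "FEResult",
    "pressure_to_mpa",
    "assemble_and_solve",
    "principal_values",
    "equivalent_strain",
    "region_maxima",
    "run_comparison_study",
    "mesh_sensitivity",
]

MMHG_TO_MPA = 133.3224e-6


def pressure_to_mpa(p_mmhg: float) -> float:
    """Convert a pressure from mmHg to MPa (1 mmHg = 133.3224 Pa)."""
    if p_mmhg < 0:
        raise ValueError("pressure must be nonnegative")
    return p_mmhg * MMHG_TO_MPA


# --- shape functions --------------------------------------------------------

_CORNERS = np.array(
    [
        (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
        (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
    ],
    dtype=float,
)
_NODES20 = np.vstack([_CORNERS, 0.5 * (_CORNERS[HEX_EDGES[:, 0]] + _CORNERS[HEX_EDGES[:, 1]])])


def shape8(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear shape functions: values (q, 8) and derivatives (q, 8, 3)."""
    pts = np.atleast_2d(pts)
    q = len(pts)
    N = np.empty((q, 8))
    dN = np.empty((q, 8, 3))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    for a, (xa, ya, za) in enumerate(_CORNERS):
        N[:, a] = 0.125 * (1 + x * xa) * (1 + y * ya) * (1 + z * za)
        dN[:, a, 0] = 0.125 * xa * (1 + y * ya) * (1 + z * za)
        dN[:, a, 1] = 0.125 * ya * (1 + x * xa) * (1 + z * za)
        dN[:, a, 2] = 0.125 * za * (1 + x * xa) * (1 + y * ya)
    return N, dN


def shape20(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """20-node serendipity shape functions: values (q, 20), derivatives (q, 20, 3)."""
    pts = np.atleast_2d(pts)
    q = len(pts)
    N = np.empty((q, 20))
    dN = np.empty((q, 20, 3))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    for a in range(8):
        xa, ya, za = _NODES20[a]
        s = x * xa + y * ya + z * za
        N[:, a] = 0.125 * (1 + x * xa) * (1 + y * ya) * (1 + z * za) * (s - 2)
        dN[:, a, 0] = 0.125 * xa * (1 + y * ya) * (1 + z * za) * (2 * x * xa + y * ya + z * za - 1)
        dN[:, a, 1] = 0.125 * ya * (1 + x * xa) * (1 + z * za) * (2 * y * ya + x * xa + z * za - 1)
        dN[:, a, 2] = 0.125 * za * (1 + x * xa) * (1 + y * ya) * (2 * z * za + x * xa + y * ya - 1)
    for a in range(8, 20):
        xa, ya, za = _NODES20[a]
        if xa == 0.0:
            N[:, a] = 0.25 * (1 - x**2) * (1 + y * ya) * (1 + z * za)
            dN[:, a, 0] = -0.5 * x * (1 + y * ya) * (1 + z * za)
            dN[:, a, 1] = 0.25 * (1 - x**2) * ya * (1 + z * za)
            dN[:, a, 2] = 0.25 * (1 - x**2) * (1 + y * ya) * za
        elif ya == 0.0:
            N[:, a] = 0.25 * (1 + x * xa) * (1 - y**2) * (1 + z * za)
            dN[:, a, 0] = 0.25 * xa * (1 - y**2) * (1 + z * za)
            dN[:, a, 1] = -0.5 * y * (1 + x * xa) * (1 + z * za)
            dN[:, a, 2] = 0.25 * (1 + x * xa) * (1 - y**2) * za
        else:
            N[:, a] = 0.25 * (1 + x * xa) * (1 + y * ya) * (1 - z**2)
            dN[:, a, 0] = 0.25 * xa * (1 + y * ya) * (1 - z**2)
            dN[:, a, 1] = 0.25 * (1 + x * xa) * ya * (1 - z**2)
            dN[:, a, 2] = -0.5 * z * (1 + x * xa) * (1 + y * ya)
    return N, dN


def _gauss1d(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def gauss_points(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss rule on [-1, 1]^3: points (n^3, 3), weights (n^3,)."""
    x, w = _gauss1d(n)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    W = np.einsum("i,j,k->ijk", w, w, w)
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1), W.ravel()


# quad face shape functions (pressure integration)

def quad_shape(pts: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear (4) or serendipity (8) quad shape functions and derivatives."""
    pts = np.atleast_2d(pts)
    q = len(pts)
    u, v = pts[:, 0], pts[:, 1]
    cn = np.array([(-1, -1), (1, -1), (1, 1), (-1, 1)], dtype=float)
    if order == 4:
        N = np.empty((q, 4))
        dN = np.empty((q, 4, 2))
        for a, (ua, va) in enumerate(cn):
            N[:, a] = 0.25 * (1 + u * ua) * (1 + v * va)
            dN[:, a, 0] = 0.25 * ua * (1 + v * va)
            dN[:, a, 1] = 0.25 * va * (1 + u * ua)
        return N, dN
    mids = 0.5 * (cn + np.roll(cn, -1, axis=0))  # (0,-1),(1,0),(0,1),(-1,0)
    N = np.empty((q, 8))
    dN = np.empty((q, 8, 2))
    for a, (ua, va) in enumerate(cn):
        N[:, a] = 0.25 * (1 + u * ua) * (1 + v * va) * (u * ua + v * va - 1)
        dN[:, a, 0] = 0.25 * ua * (1 + v * va) * (2 * u * ua + v * va)
        dN[:, a, 1] = 0.25 * va * (1 + u * ua) * (2 * v * va + u * ua)
    for a, (ua, va) in enumerate(mids, start=4):
        if ua == 0.0:
            N[:, a] = 0.5 * (1 - u**2) * (1 + v * va)
            dN[:, a, 0] = -u * (1 + v * va)
            dN[:, a, 1] = 0.5 * (1 - u**2) * va
        else:
            N[:, a] = 0.5 * (1 + u * ua) * (1 - v**2)
            dN[:, a, 0] = 0.5 * ua * (1 - v**2)
            dN[:, a, 1] = -v * (1 + u * ua)
    return N, dN


# --- problem / result containers -------------------------------------------

@dataclass
class FEProblem:
    """Linear elastostatic problem on a hexahedral mesh.

    ``elasticity`` is the (m, 6, 6) per-element global-frame stiffness (MPa,
    Voigt order xx, yy, zz, yz, xz, xy with engineering shears).
    ``fixed_nodes`` are clamped in all three components; ``prescribed`` may
    pin arbitrary single dofs (indices into the 3n displacement vector).
    ``pressure_faces`` receive the uniform normal pressure ``pressure_mmhg``
    acting against the outward solid normal (inflation for interior faces).
    """

    mesh: HexMesh
    elasticity: np.ndarray
    fixed_nodes: np.ndarray | None = None
    prescribed: tuple[np.ndarray, np.ndarray] | None = None  # (dofs, values)
    pressure_mmhg: float = 0.0
    pressure_faces: np.ndarray | None = None  # (k, 2) (elem, local face)
    face_tractions: list = field(default_factory=list)  # [((k, 2), (3,) MPa)]

    def validate(self) -> None:
        m = self.mesh.n_elements
        if self.elasticity.shape != (m, 6, 6):
            raise ValueError("elasticity must be (n_elements, 6, 6)")
        has_dirichlet = (self.fixed_nodes is not None and len(self.fixed_nodes) > 0) or (
            self.prescribed is not None and len(self.prescribed[0]) > 0
        )
        if not has_dirichlet:
            raise ValueError("problem needs at least one constrained dof")
        if self.pressure_mmhg and (
            self.pressure_faces is None or len(self.pressure_faces) == 0
        ):
            raise ValueError("pressure load requires a nonempty face set")


@dataclass
class FEResult:
    """Solution fields: nodal displacements plus quadrature-point tensors."""

    u: np.ndarray  # (n, 3) mm
    strain: np.ndarray  # (m, q, 6) Voigt engineering
    stress: np.ndarray  # (m, q, 6) MPa
    f_ext: np.ndarray  # (3n,) applied loads
    residual: float  # |K u - f| / max(|f|, 1) over free dofs
    equilibrium_error: float  # |sum reactions + sum applied| / |applied|
    strain_energy: float

    @property
    def displacement_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.u, axis=1)


def _element_dofs(conn: np.ndarray) -> np.ndarray:
    """(m, 3*nodes) global dof indices per element."""
    m, nn = conn.shape
    d = np.empty((m, 3 * nn), dtype=np.int64)
    d[:, 0::3] = 3 * conn
    d[:, 1::3] = 3 * conn + 1
    d[:, 2::3] = 3 * conn + 2
    return d


def _b_matrices(gradN: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices (c, q, 6, 3*nodes) from shape gradients.

    ``gradN`` has shape (c, q, 3, nodes) with rows d/dx, d/dy, d/dz.
    """
    c, q, _, nn = gradN.shape
    B = np.zeros((c, q, 6, 3 * nn))
    gx, gy, gz = gradN[:, :, 0], gradN[:, :, 1], gradN[:, :, 2]
    B[:, :, 0, 0::3] = gx
    B[:, :, 1, 1::3] = gy
    B[:, :, 2, 2::3] = gz
    B[:, :, 3, 1::3] = gz
    B[:, :, 3, 2::3] = gy
    B[:, :, 4, 0::3] = gz
    B[:, :, 4, 2::3] = gx
    B[:, :, 5, 0::3] = gy
    B[:, :, 5, 1::3] = gx
    return B


def _assemble_stiffness(mesh: HexMesh, C: np.ndarray, chunk: int = 256):
    """Global sparse stiffness; also returns per-element B matrices context.

    20-node elements: full 3x3x3 quadrature.  8-node: 2x2x2 with B-bar mean
    dilatation to avoid volumetric locking near incompressibility.
    """
    order = mesh.order
    if order == 20:
        pts, w = gauss_points(3)
        _, dN = shape20(pts)
    else:
        pts, w = gauss_points(2)
        _, dN = shape8(pts)
    conn = mesh.elements
    nodes = mesh.nodes
    m = len(conn)
    ndof = 3 * mesh.n_nodes
    edof = _element_dofs(conn)
    rows_all, cols_all, vals_all = [], [], []
    bctx = []  # (slice, B, wdet) chunks for strain recovery
    for start in range(0, m, chunk):
        sl = slice(start, min(start + chunk, m))
        coords = nodes[conn[sl]]  # (c, nn, 3)
        J = np.einsum("qad,cak->cqdk", dN, coords)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            bad = np.nonzero(np.any(detJ <= 0, axis=1))[0] + start
            raise ValueError(f"nonpositive Jacobian in elements {bad[:10].tolist()}")
        rhs = np.broadcast_to(dN.transpose(0, 2, 1), (sl.stop - sl.start,) + (len(w), 3, dN.shape[1]))
        gradN = np.linalg.solve(J, rhs)  # (c, q, 3, nn)
        B = _b_matrices(gradN)
        if order == 8:
            # B-bar: replace the volumetric part with its element average
            vol = np.einsum("cq,q->c", detJ, w)
            # b[c, q, 3*nn]: b[3a+k] = gradN[k, a]
            c_, q_, _, nn_ = gradN.shape
            b = np.zeros((c_, q_, 3 * nn_))
            b[:, :, 0::3] = gradN[:, :, 0]
            b[:, :, 1::3] = gradN[:, :, 1]
            b[:, :, 2::3] = gradN[:, :, 2]
            bbar = np.einsum("cqi,cq,q->ci", b, detJ, w) / vol[:, None]
            corr = (bbar[:, None, :] - b) / 3.0
            for r in range(3):
                B[:, :, r, :] += corr
        wdet = detJ * w[None, :]
        ke = np.einsum("cqia,cij,cqjb,cq->cab", B, C[sl], B, wdet, optimize=True)
        nd = ke.shape[1]
        r = np.repeat(edof[sl], nd, axis=1).ravel()
        col = np.tile(edof[sl], (1, nd)).ravel()
        rows_all.append(r)
        cols_all.append(col)
        vals_all.append(ke.ravel())
        bctx.append((sl, B, wdet))
    K = sp.coo_matrix(
        (np.concatenate(vals_all), (np.concatenate(rows_all), np.concatenate(cols_all))),
        shape=(ndof, ndof),
    ).tocsr()
    return K, bctx


def _face_loads(mesh: HexMesh, faces: np.ndarray, pressure_mpa: float,
                traction: np.ndarray | None = None) -> np.ndarray:
    """Consistent nodal forces for pressure (or fixed traction) on quad faces."""
    ndof = 3 * mesh.n_nodes
    f = np.zeros(ndof)
    gp1, gw1 = _gauss1d(3)
    U, V = np.meshgrid(gp1, gp1, indexing="ij")
    W = np.outer(gw1, gw1).ravel()
    uv = np.stack([U.ravel(), V.ravel()], axis=1)
    nfn = 4 if mesh.order == 8 else 8
    N, dN = quad_shape(uv, nfn)
    centroid_all = mesh.nodes[mesh.elements[:, :8]].mean(axis=1)
    Nc, _ = quad_shape(np.zeros((1, 2)), nfn)
    for elem, face in faces:
        ids = mesh.face_nodes(int(elem), int(face))
        X = mesh.nodes[ids]  # (nfn, 3)
        Xu = np.einsum("qad,ak->qdk", dN, X)  # (q, 2, 3)
        nvec = np.cross(Xu[:, 0], Xu[:, 1])  # (q, 3) area-weighted param normal
        xc = (Nc @ X)[0]
        sign = 1.0 if np.dot(np.cross(Xu[0, 0], Xu[0, 1]), xc - centroid_all[elem]) > 0 else -1.0
        if traction is None:
            tvec = -pressure_mpa * sign * nvec  # (q, 3), t = -p n_out dA
        else:
            tvec = traction[None, :] * np.linalg.norm(nvec, axis=1)[:, None]
        contrib = np.einsum("q,qa,qk->ak", W, N, tvec)
        for a, nid in enumerate(ids):
            f[3 * nid : 3 * nid + 3] += contrib[a]
    return f


def assemble_and_solve(problem: FEProblem) -> FEResult:
    """Assemble, apply boundary conditions, solve, and recover fields."""
    problem.validate()
    mesh = problem.mesh
    ndof = 3 * mesh.n_nodes
    K, bctx = _assemble_stiffness(mesh, problem.elasticity)

    f_ext = np.zeros(ndof)
    if problem.pressure_mmhg and problem.pressure_faces is not None:
        f_ext += _face_loads(mesh, problem.pressure_faces, pressure_to_mpa(problem.pressure_mmhg))
    for faces, t in problem.face_tractions:
        f_ext += _face_loads(mesh, np.asarray(faces), 0.0, traction=np.asarray(t, dtype=float))

    fixed = np.zeros(ndof, dtype=bool)
    uvals = np.zeros(ndof)
    if problem.fixed_nodes is not None and len(problem.fixed_nodes):
        idx = np.asarray(problem.fixed_nodes, dtype=np.int64)
        for k in range(3):
            fixed[3 * idx + k] = True
    if problem.prescribed is not None:
        dofs, vals = problem.prescribed
        fixed[np.asarray(dofs, dtype=np.int64)] = True
        uvals[np.asarray(dofs, dtype=np.int64)] = vals
    free = ~fixed

    Kcsc = K.tocsc()
    Kff = Kcsc[free][:, free]
    rhs = f_ext[free] - Kcsc[free][:, fixed] @ uvals[fixed]
    lu = spla.splu(Kff.tocsc())
    uf = lu.solve(rhs)
    u = uvals.copy()
    u[free] = uf

    res_free = Kff @ uf - rhs
    residual = float(np.linalg.norm(res_free) / max(np.linalg.norm(rhs), 1e-30))
    # reactions at constrained dofs; global balance against applied loads
    Ku = K @ u
    reactions = (Ku - f_ext)[fixed]
    total_applied = f_ext.reshape(-1, 3).sum(axis=0)
    total_reaction = (Ku - f_ext).reshape(-1, 3)[fixed.reshape(-1, 3).any(axis=1)].sum(axis=0)
    denom = max(np.abs(f_ext).sum(), 1e-30)
    equilibrium_error = float(np.linalg.norm(total_applied + total_reaction) / denom) if np.abs(f_ext).sum() > 0 else float(np.linalg.norm(total_reaction))

    # strain/stress recovery at quadrature points
    conn = mesh.elements
    edof = _element_dofs(conn)
    m = mesh.n_elements
    nq = bctx[0][1].shape[1]
    strain = np.empty((m, nq, 6))
    for sl, B, wdet in bctx:
        ue = u[edof[sl]]
        strain[sl] = np.einsum("cqia,ca->cqi", B, ue)
    stress = np.einsum("cij,cqj->cqi", problem.elasticity, strain)
    energy = 0.0
    for sl, B, wdet in bctx:
        energy += 0.5 * np.einsum("cqi,cqi,cq->", stress[sl], strain[sl], wdet)
    return FEResult(
        u=u.reshape(-1, 3),
        strain=strain,
        stress=stress,
        f_ext=f_ext,
        residual=residual,
        equilibrium_error=equilibrium_error,
        strain_energy=float(energy),
    )


# --- postprocessing ---------------------------------------------------------

def voigt_to_matrix(v: np.ndarray, engineering: bool = False) -> np.ndarray:
    """(..., 6) Voigt -> (..., 3, 3) symmetric matrices."""
    v = np.asarray(v, dtype=float)
    half = 0.5 if engineering else 1.0
    M = np.empty(v.shape[:-1] + (3, 3))
    M[..., 0, 0] = v[..., 0]
    M[..., 1, 1] = v[..., 1]
    M[..., 2, 2] = v[..., 2]
    M[..., 1, 2] = M[..., 2, 1] = half * v[..., 3]
    M[..., 0, 2] = M[..., 2, 0] = half * v[..., 4]
    M[..., 0, 1] = M[..., 1, 0] = half * v[..., 5]
    return M


def principal_values(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric 3x3 tensors, sorted descending."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape[-2:] != (3, 3):
        raise ValueError("expected (..., 3, 3) tensors")
    if np.max(np.abs(tensor - np.swapaxes(tensor, -1, -2))) > 1e-9 * max(
        1.0, float(np.max(np.abs(tensor)))
    ):
        raise ValueError("tensor not symmetric")
    ev = np.linalg.eigvalsh(tensor)
    return ev[..., ::-1]


def equivalent_strain(strain_voigt: np.ndarray) -> np.ndarray:
    """Von Mises equivalent strain sqrt(2/3 e:e) of the strain deviator.

    Input in Voigt engineering form (gamma = 2 eps for shears).
    """
    e = voigt_to_matrix(np.asarray(strain_voigt), engineering=True)
    tr = np.trace(e, axis1=-2, axis2=-1)
    dev = e - tr[..., None, None] / 3.0 * np.eye(3)
    return np.sqrt(2.0 / 3.0 * np.einsum("...ij,...ij->...", dev, dev))


_REGION_NAMES = {0: "onh_adjacent", 1: "peripapillary", 2: "peripheral"}


def region_maxima(result: FEResult, labels: np.ndarray, mesh: HexMesh) -> pd.DataFrame:
    """Per-region maxima of |u|, principal stress/strain and equivalent strain.

    Displacement maxima are taken over the nodes of each region's elements;
    tensor maxima over their quadrature points.
    """
    umag = result.displacement_magnitude
    s_p = principal_values(voigt_to_matrix(result.stress))[..., 0]  # (m, q)
    e_p = principal_values(voigt_to_matrix(result.strain, engineering=True))[..., 0]
    e_eq = equivalent_strain(result.strain)
    rows = []
    for region in np.unique(labels):
        sel = labels == region
        if not sel.any():
            raise ValueError(f"empty region {region}")
        node_ids = np.unique(mesh.elements[sel].ravel())
        rows.append(
            {
                "region": _REGION_NAMES.get(int(region), str(region)),
                "max_displacement_mm": float(umag[node_ids].max()),
                "max_principal_stress_mpa": float(s_p[sel].max()),
                "max_principal_strain": float(e_p[sel].max()),
                "max_equivalent_strain": float(e_eq[sel].max()),
            }
        )
    return pd.DataFrame(rows).set_index("region")


# --- study drivers ----------------------------------------------------------

def solve_sclera_model(
    shell,
    scheme: int | str = 0,
    isotropic: bool = False,
    iop_mmhg: float = 30.0,
    u1: float = 0.15,
    u2: float = 0.45,
):
    """Solve one sclera model (isotropic or fibre-rotation scheme k) on a MeshedShell.

    Returns (result, labels, frames). The equator ring is fully fixed and
    the IOP acts on the inner surface face set.
    """
    from .material_frames import (
        SCLERA_ISOTROPIC,
        SCLERA_ORTHOTROPIC,
        apply_rotation_scheme,
        assign_local_frames,
        label_regions,
    )

    mesh = shell.mesh
    labels = label_regions(mesh, shell.outer, shell.field_outer, u1=u1, u2=u2)
    if isotropic:
        frames = None
        C = build_stiffness_batch(SCLERA_ISOTROPIC, None, mesh.n_elements)
    else:
        if isinstance(scheme, str):
            scheme = 0 if scheme in ("r0", "perfect") else int(str(scheme).lstrip("r"))
        frames = assign_local_frames(mesh, shell.outer, shell.field_outer)
        frames = apply_rotation_scheme(frames, labels, scheme)
        C = build_stiffness_batch(SCLERA_ORTHOTROPIC, frames, mesh.n_elements)
    problem = FEProblem(
        mesh=mesh,
        elasticity=C,
        fixed_nodes=mesh.node_sets["equator_ring"],
        pressure_mmhg=iop_mmhg,
        pressure_faces=mesh.face_sets["inner_surface"],
    )
    result = assemble_and_solve(problem)
    return result, labels, frames


def run_comparison_study(shell, iop_mmhg: float = 30.0, schemes=None) -> pd.DataFrame:
    """The 12-model comparison: isotropic plus fibre rotations k = 0..10.

    All models share one mesh; each row holds the region-wise maxima of the
    solved fields for one material model.
    """
    if schemes is None:
        schemes = list(range(11))
    frames_rows = []
    res_iso, labels, _ = solve_sclera_model(shell, isotropic=True, iop_mmhg=iop_mmhg)
    tab = region_maxima(res_iso, labels, shell.mesh)
    for region, row in tab.iterrows():
        frames_rows.append({"model": "isotropic", "region": region, **row.to_dict()})
    for k in schemes:
        res, labels, _ = solve_sclera_model(shell, scheme=k, iop_mmhg=iop_mmhg)
        tab = region_maxima(res, labels, shell.mesh)
        name = "perfect" if k == 0 else f"r{k}"
        for region, row in tab.iterrows():
            frames_rows.append({"model": name, "region": region, **row.to_dict()})
    return pd.DataFrame(frames_rows)


def mesh_sensitivity(shell_a, shell_b, iop_mmhg: float = 30.0) -> dict:
    """Relative change (%) of max |u| and max principal stress between two meshes.

    ``shell_b`` is the finer (reference) discretization.
    """
    res_a, _, _ = solve_sclera_model(shell_a, scheme=0, iop_mmhg=iop_mmhg)
    res_b, _, _ = solve_sclera_model(shell_b, scheme=0, iop_mmhg=iop_mmhg)

    def metrics(res):
        umax = float(res.displacement_magnitude.max())
        smax = float(principal_values(voigt_to_matrix(res.stress))[..., 0].max())
        return umax, smax

    ua, sa = metrics(res_a)
    ub, sb = metrics(res_b)
    return {
        "displacement_change_pct": abs(ub - ua) / ub * 100.0,
        "stress_change_pct": abs(sb - sa) / sb * 100.0,
        "coarse": {"max_displacement_mm": ua, "max_principal_stress_mpa": sa},
        "fine": {"max_displacement_mm": ub, "max_principal_stress_mpa": sb},
    }
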