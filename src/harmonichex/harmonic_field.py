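"""Discrete harmonic fields on triangle surfaces.

The field f solves the umbrella-operator equation (L f)_i = 0 at every free
vertex, where L uses the cotangent ("discrete harmonic") edge weights
w_ij = (cot a_ij + cot b_ij) / 2, with a_ij, b_ij the angles opposite edge
(i, j) in its one or two incident triangles.  Dirichlet values are pinned on
the boundary loops — by convention 0 on the ONH canal ring and 1 on the
equator ring — and the reduced symmetric positive-definite system A x = b is
solved by Jacobi-preconditioned conjugate gradients (small systems go
through a direct sparse factorization for test-grade exactness).

Because all weights are nonnegative on well-shaped meshes, the solution
obeys the discrete maximum principle: extrema occur only at constrained
vertices.  Negative weights from obtuse triangles are kept (not clamped) and
their count is reported on the operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh_io import TriSurface, extract_boundary_loops

__all__ = [
    "LaplacianOperator",
    "HarmonicConstraints",
    "cotangent_laplacian",
    "solve_harmonic",
    "gradient",
    "loop_constraints",
]

_DIRECT_SOLVE_LIMIT = 50_000  # unknowns; above this fall back to PCG


@dataclass
class LaplacianOperator:
    """Cotangent Laplacian: L_ii = sum_k w_ik, L_ij = -w_ij, rows sum to zero."""

    matrix: sp.csr_matrix  # (n, n) symmetric
    edge_weights: np.ndarray  # (E,) aligned with surface.edges
    n_negative_weights: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def cotangent_laplacian(surface: TriSurface, clamp_negative: bool = False) -> LaplacianOperator:
    """Assemble the cotangent-weight Laplacian of a triangle surface.

    Boundary edges have a single incident triangle and use the one available
    cotangent.  ``clamp_negative`` optionally clamps negative weights to zero
    (off by default: clamping changes the operator).
    """
    v = surface.vertices
    t = surface.triangles
    n = len(v)
    # cot of angle at corner k, opposite edge (k+1, k+2)
    cots = np.empty((len(t), 3))
    for k in range(3):
        a = v[t[:, (k + 1) % 3]] - v[t[:, k]]
        b = v[t[:, (k + 2) % 3]] - v[t[:, k]]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        if np.any(cross < 1e-300):
            raise ValueError("degenerate triangle: cotangent undefined")
        cots[:, k] = np.sum(a * b, axis=1) / cross

    rows, cols, vals = [], [], []
    for k in range(3):
        i = t[:, (k + 1) % 3]
        j = t[:, (k + 2) % 3]
        w = 0.5 * cots[:, k]
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([w, w])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if clamp_negative:
        W.data = np.maximum(W.data, 0.0)
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W
    # per-undirected-edge weights, aligned with surface.edges
    e = surface.edges
    ew = np.asarray(W[e[:, 0], e[:, 1]]).ravel()
    return LaplacianOperator(L.tocsr(), ew, int(np.sum(ew < 0)))


@dataclass
class HarmonicConstraints:
    """Dirichlet data: per-vertex indices and values on the boundary loops."""

    indices: np.ndarray  # (c,) vertex indices
    values: np.ndarray  # (c,) scalar values

    def validate(self, surface: TriSurface) -> None:
        if len(np.unique(self.values)) < 2:
            raise ValueError("need at least two distinct constraint values")
        bverts = set()
        for lp in extract_boundary_loops(surface):
            bverts.update(int(i) for i in lp.vertices)
        if not set(int(i) for i in self.indices) <= bverts:
            raise ValueError("constrained vertices must lie on boundary loops")


def loop_constraints(
    surface: TriSurface, onh_value: float = 0.0, equator_value: float = 1.0
) -> HarmonicConstraints:
    """Standard sclera constraints: equator loop (longest) -> 1, ONH loop -> 0."""
    loops = extract_boundary_loops(surface)
    if len(loops) != 2:
        raise ValueError(f"expected 2 boundary loops, found {len(loops)}")
    eq, onh = loops[0], loops[-1]
    idx = np.concatenate([eq.vertices, onh.vertices])
    vals = np.concatenate(
        [np.full(len(eq.vertices), equator_value), np.full(len(onh.vertices), onh_value)]
    )
    return HarmonicConstraints(idx, vals)


def solve_harmonic(
    surface: TriSurface,
    constraints: HarmonicConstraints,
    tol: float = 1e-10,
    operator: LaplacianOperator | None = None,
    validate: bool = True,
) -> np.ndarray:
    """Solve the Dirichlet-constrained harmonic problem; returns per-vertex f.

    Constraint rows/columns are eliminated to the right-hand side, leaving a
    positive-definite system on the free vertices.  Constrained vertices hold
    their values exactly.
    """
    if validate:
        constraints.validate(surface)
    op = operator or cotangent_laplacian(surface)
    L = op.matrix
    n = L.shape[0]
    fixed = np.zeros(n, dtype=bool)
    fixed[constraints.indices] = True
    xc = np.zeros(n)
    xc[constraints.indices] = constraints.values
    free = ~fixed
    if not free.any():
        return xc
    A = L[free][:, free].tocsc()
    b = -L[free][:, fixed] @ xc[fixed]
    nf = int(free.sum())
    if nf <= _DIRECT_SOLVE_LIMIT:
        xf = spla.spsolve(A, b)
    else:
        M = sp.diags(1.0 / A.diagonal())
        xf, info = spla.cg(A, b, rtol=tol, atol=0.0, M=M, maxiter=20 * nf)
        if info != 0:
            raise RuntimeError(f"PCG failed to converge (info={info})")
    f = xc.copy()
    f[free] = xf
    # residual check at free vertices
    res = np.abs((L @ f)[free])
    scale = max(np.linalg.norm(f), 1.0)
    if res.size and res.max() > 1e-6 * scale:
        raise RuntimeError("harmonic residual too large; system may be singular")
    return f


def gradient(surface: TriSurface, f: np.ndarray) -> np.ndarray:
    """Per-triangle gradient (1/mm) of the piecewise-linear interpolant of f.

    Constant inside each triangle and tangent to its plane:
    grad f = sum_k f_k (n x e_k) / (2 A), with e_k the edge opposite vertex k.
    """
    v = surface.vertices
    t = surface.triangles
    f = np.asarray(f, dtype=float)
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    nrm = np.cross(p1 - p0, p2 - p0)
    area2 = np.linalg.norm(nrm, axis=1, keepdims=True)
    nhat = nrm / area2
    g = (
        f[t[:, 0], None] * np.cross(nhat, p2 - p1)
        + f[t[:, 1], None] * np.cross(nhat, p0 - p2)
        + f[t[:, 2], None] * np.cross(nhat, p1 - p0)
    ) / area2
    return g
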