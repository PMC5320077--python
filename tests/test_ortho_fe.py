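import numpy as np
import pytest

from harmonichex.hex_mesher import convert_to_20node
from harmonichex.material_frames import (
    IsotropicMaterial,
    OrthotropicMaterial,
    build_stiffness_batch,
)
from harmonichex.mesh_io import HexMesh
from harmonichex.ortho_fe import (
    FEProblem,
    assemble_and_solve,
    equivalent_strain,
    mesh_sensitivity,
    pressure_to_mpa,
    principal_values,
    region_maxima,
    shape8,
    shape20,
    voigt_to_matrix,
)
from harmonichex.synthetic_geometry import make_mapped_spherical_shell


def _unit_cube(order=8):
    nodes = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        float,
    )
    mesh = HexMesh(nodes, np.arange(8)[None, :])
    return convert_to_20node(mesh) if order == 20 else mesh


def _block(nx, order=8):
    """nx^3 unit blocks filling [0, 1]^3."""
    xs = np.linspace(0, 1, nx + 1)
    idx = {}
    nodes = []
    for k, z in enumerate(xs):
        for j, y in enumerate(xs):
            for i, x in enumerate(xs):
                idx[(i, j, k)] = len(nodes)
                nodes.append((x, y, z))
    elems = []
    for k in range(nx):
        for j in range(nx):
            for i in range(nx):
                elems.append(
                    [
                        idx[(i, j, k)], idx[(i + 1, j, k)], idx[(i + 1, j + 1, k)], idx[(i, j + 1, k)],
                        idx[(i, j, k + 1)], idx[(i + 1, j, k + 1)], idx[(i + 1, j + 1, k + 1)], idx[(i, j + 1, k + 1)],
                    ]
                )
    mesh = HexMesh(np.array(nodes, float), np.array(elems))
    return convert_to_20node(mesh) if order == 20 else mesh


def _symmetry_dofs(mesh, tol=1e-9):
    dofs = []
    for i, p in enumerate(mesh.nodes):
        for ax in range(3):
            if abs(p[ax]) < tol:
                dofs.append(3 * i + ax)
    return np.array(sorted(set(dofs)))


def lame_radial_displacement(r, a, b, p, E, nu):
    """Thick-walled sphere under internal pressure: closed-form u_r."""
    return p * a**3 * r / (E * (b**3 - a**3)) * ((1 - 2 * nu) + (1 + nu) * b**3 / (2 * r**3))


class TestPressureConversion:
    def test_values(self):
        assert pressure_to_mpa(0.0) == 0.0
        assert pressure_to_mpa(30.0) == pytest.approx(0.00399967, abs=1e-8)
        assert pressure_to_mpa(760.0) == pytest.approx(0.101325, rel=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pressure_to_mpa(-1.0)


class TestShapeFunctions:
    @pytest.mark.parametrize("fn,n", [(shape8, 8), (shape20, 20)])
    def test_partition_of_unity_and_kronecker(self, fn, n):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-1, 1, (10, 3))
        N, dN = fn(pts)
        assert np.max(np.abs(N.sum(axis=1) - 1)) < 1e-12
        assert np.max(np.abs(dN.sum(axis=1))) < 1e-12
        from harmonichex.ortho_fe import _CORNERS, _NODES20

        nodes = _CORNERS if n == 8 else _NODES20
        Nn, _ = fn(nodes)
        assert np.max(np.abs(Nn - np.eye(n))) < 1e-12

    @pytest.mark.parametrize("fn", [shape8, shape20])
    def test_derivatives_match_finite_differences(self, fn):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-0.9, 0.9, (5, 3))
        N, dN = fn(pts)
        h = 1e-6
        for d in range(3):
            dp = np.zeros(3)
            dp[d] = h
            Np, _ = fn(pts + dp)
            Nm, _ = fn(pts - dp)
            fd = (Np - Nm) / (2 * h)
            assert np.max(np.abs(fd - dN[:, :, d])) < 1e-8


class TestSingleElement:
    @pytest.mark.parametrize("order", [8, 20])
    def test_uniaxial_traction_closed_form(self, order):
        """Axial strain sigma/E and transverse -nu sigma/E to 1e-8."""
        mesh = _unit_cube(order)
        E, nu, sigma = 3.8, 0.49, 0.01
        C = build_stiffness_batch(IsotropicMaterial(E, nu), None, 1)
        faces = np.array([[0, 1]])  # +x face
        prob = FEProblem(
            mesh,
            C,
            prescribed=(_symmetry_dofs(mesh), np.zeros(len(_symmetry_dofs(mesh)))),
            face_tractions=[(faces, np.array([sigma, 0, 0]))],
        )
        res = assemble_and_solve(prob)
        assert np.max(np.abs(res.strain[0, :, 0] - sigma / E)) < 1e-8
        assert np.max(np.abs(res.strain[0, :, 1] + nu * sigma / E)) < 1e-8
        assert np.max(np.abs(res.strain[0, :, 2] + nu * sigma / E)) < 1e-8
        assert res.residual < 1e-8

    def test_rigid_translation_zero_energy(self):
        mesh = _unit_cube(20)
        C = build_stiffness_batch(IsotropicMaterial(3.8, 0.49), None, 1)
        dofs = np.arange(3 * mesh.n_nodes)
        shift = np.tile([0.1, -0.2, 0.3], mesh.n_nodes)
        prob = FEProblem(mesh, C, prescribed=(dofs, shift))
        res = assemble_and_solve(prob)
        assert res.strain_energy < 1e-10
        assert np.max(np.abs(res.strain)) < 1e-10


class TestPatchTest:
    @pytest.mark.parametrize("order", [8, 20])
    @pytest.mark.parametrize("nx", [1, 2])
    def test_affine_displacement_reproduced_exactly(self, order, nx):
        """Affine boundary displacement yields the exact constant strain state."""
        mesh = _block(nx, order)
        C = build_stiffness_batch(OrthotropicMaterial(), np.broadcast_to(np.eye(3), (mesh.n_elements, 3, 3)).copy(), mesh.n_elements)
        A = np.array([[1e-3, 4e-4, -2e-4], [4e-4, -5e-4, 3e-4], [-2e-4, 3e-4, 8e-4]])
        u_exact = mesh.nodes @ A.T
        # prescribe on boundary nodes only
        on_bnd = np.any((np.abs(mesh.nodes) < 1e-12) | (np.abs(mesh.nodes - 1) < 1e-12), axis=1)
        bnd = np.nonzero(on_bnd)[0]
        dofs = np.concatenate([3 * bnd, 3 * bnd + 1, 3 * bnd + 2])
        vals = np.concatenate([u_exact[bnd, 0], u_exact[bnd, 1], u_exact[bnd, 2]])
        prob = FEProblem(mesh, C, prescribed=(dofs, vals))
        res = assemble_and_solve(prob)
        assert np.max(np.abs(res.u - u_exact)) < 1e-9
        exact_strain = np.array([A[0, 0], A[1, 1], A[2, 2], 2 * A[1, 2], 2 * A[0, 2], 2 * A[0, 1]])
        assert np.max(np.abs(res.strain - exact_strain)) < 1e-9


class TestLameSphere:
    def test_radial_displacement_convergence(self):
        """Monotone convergence to the thick-sphere closed form; <2% at finest."""
        a, b, p_mmhg = 11.0, 12.0, 30.0
        p = pressure_to_mpa(p_mmhg)
        E, nu = 3.8, 0.49
        errs = []
        for n_ang, n_rad in [(2, 1), (4, 2), (8, 3)]:
            mesh = convert_to_20node(make_mapped_spherical_shell(a, b, n_ang, n_rad))
            C = build_stiffness_batch(IsotropicMaterial(E, nu), None, mesh.n_elements)
            dofs = []
            for i, pt in enumerate(mesh.nodes):
                for ax in range(3):
                    if abs(pt[ax]) < 1e-9:
                        dofs.append(3 * i + ax)
            dofs = np.array(sorted(set(dofs)))
            prob = FEProblem(
                mesh, C,
                prescribed=(dofs, np.zeros(len(dofs))),
                pressure_mmhg=p_mmhg,
                pressure_faces=mesh.face_sets["inner"],
            )
            res = assemble_and_solve(prob)
            r = np.linalg.norm(mesh.nodes, axis=1)
            ur = np.sum(res.u * mesh.nodes, axis=1) / r
            sel_in = np.abs(r - a) < 1e-6
            sel_out = np.abs(r - b) < 1e-6
            e_in = abs(ur[sel_in].mean() / lame_radial_displacement(a, a, b, p, E, nu) - 1)
            e_out = abs(ur[sel_out].mean() / lame_radial_displacement(b, a, b, p, E, nu) - 1)
            errs.append(max(e_in, e_out))
            assert res.equilibrium_error < 1e-8
        assert errs[2] < errs[1] < errs[0]
        assert errs[2] < 0.02


class TestPostprocessing:
    def test_principal_values_sorted_and_rotation_invariant(self):
        assert np.allclose(principal_values(np.diag([3.0, 1.0, 2.0])), [3, 2, 1])
        p = 2.5
        assert np.allclose(principal_values(p * np.eye(3)), [p, p, p])
        rng = np.random.default_rng(11)
        T = rng.normal(size=(3, 3))
        T = 0.5 * (T + T.T)
        ev = principal_values(T)
        roots = np.sort(np.roots(np.poly(T)))[::-1]  # characteristic polynomial oracle
        assert np.allclose(ev, roots.real, atol=1e-10)
        Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        assert np.allclose(principal_values(Q @ T @ Q.T), ev, atol=1e-10)

    def test_principal_values_rejects_asymmetric(self):
        with pytest.raises(ValueError):
            principal_values(np.array([[0, 1, 0], [0, 0, 0], [0, 0, 0.0]]))

    def test_equivalent_strain_formula(self):
        # pure volumetric: deviator vanishes
        assert equivalent_strain(np.array([0.01, 0.01, 0.01, 0, 0, 0])) == pytest.approx(0.0, abs=1e-15)
        # uniaxial strain eps with zero transverse: direct formula evaluation
        eps = 2e-3
        e = np.diag([eps, 0, 0])
        dev = e - np.trace(e) / 3 * np.eye(3)
        expected = np.sqrt(2 / 3 * np.sum(dev * dev))
        assert equivalent_strain(np.array([eps, 0, 0, 0, 0, 0])) == pytest.approx(expected, rel=1e-12)
        # rotation invariance
        rng = np.random.default_rng(5)
        E = rng.normal(size=(3, 3))
        E = 0.5 * (E + E.T)
        Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        Er = Q @ E @ Q.T

        def to_voigt(e):
            return np.array([e[0, 0], e[1, 1], e[2, 2], 2 * e[1, 2], 2 * e[0, 2], 2 * e[0, 1]])

        assert equivalent_strain(to_voigt(E)) == pytest.approx(equivalent_strain(to_voigt(Er)), rel=1e-10)

    def test_region_maxima_brute_force(self, small_shell):
        from harmonichex.ortho_fe import solve_sclera_model
        from harmonichex.material_frames import label_regions

        res, labels, _ = solve_sclera_model(small_shell, scheme=0)
        tab = region_maxima(res, labels, small_shell.mesh)
        s_p = principal_values(voigt_to_matrix(res.stress))[..., 0]
        umag = res.displacement_magnitude
        for region, name in [(0, "onh_adjacent"), (1, "peripapillary"), (2, "peripheral")]:
            sel = labels == region
            node_ids = np.unique(small_shell.mesh.elements[sel].ravel())
            assert tab.loc[name, "max_displacement_mm"] == pytest.approx(umag[node_ids].max())
            assert tab.loc[name, "max_principal_stress_mpa"] == pytest.approx(s_p[sel].max())

    def test_uniform_field_same_in_all_regions(self, small_shell):
        """A constant tensor field reports identical maxima everywhere."""
        from harmonichex.ortho_fe import FEResult

        m = small_shell.mesh.n_elements
        n = small_shell.mesh.n_nodes
        const = np.array([1e-3, -2e-4, 3e-4, 0, 0, 1e-4])
        res = FEResult(
            u=np.full((n, 3), 0.01),
            strain=np.broadcast_to(const, (m, 27, 6)).copy(),
            stress=np.broadcast_to(const * 10, (m, 27, 6)).copy(),
            f_ext=np.zeros(3 * n),
            residual=0.0,
            equilibrium_error=0.0,
            strain_energy=0.0,
        )
        labels = np.zeros(m, dtype=int)
        labels[: m // 3] = 1
        labels[m // 3 : 2 * m // 3] = 2
        tab = region_maxima(res, labels, small_shell.mesh)
        assert tab["max_displacement_mm"].nunique() == 1
        assert tab["max_principal_stress_mpa"].nunique() == 1


class TestFrameConsistency:
    def test_isotropic_solution_independent_of_frames(self, small_shell):
        """Random frames with an isotropic material match frame-free assembly."""
        from harmonichex.material_frames import rotate_stiffness

        mesh = small_shell.mesh
        m = mesh.n_elements
        rng = np.random.default_rng(19)
        frames = np.empty((m, 3, 3))
        for i in range(m):
            Q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            frames[i] = Q.T
        C_iso = IsotropicMaterial(3.8, 0.49).stiffness_local()
        C_plain = np.broadcast_to(C_iso, (m, 6, 6)).copy()
        C_framed = rotate_stiffness(C_iso, frames)
        kw = dict(
            fixed_nodes=mesh.node_sets["equator_ring"],
            pressure_mmhg=30.0,
            pressure_faces=mesh.face_sets["inner_surface"],
        )
        u0 = assemble_and_solve(FEProblem(mesh, C_plain, **kw)).u
        u1 = assemble_and_solve(FEProblem(mesh, C_framed, **kw)).u
        assert np.max(np.abs(u0 - u1)) < 1e-9 * max(np.abs(u0).max(), 1e-12)


class TestSensitivity:
    def test_identical_resolutions_zero_change(self, small_shell):
        sens = mesh_sensitivity(small_shell, small_shell)
        assert sens["displacement_change_pct"] == 0.0
        assert sens["stress_change_pct"] == 0.0

    def test_changes_match_hand_recomputation(self, sclera_surfaces):
        from harmonichex.hex_mesher import generate_shell_mesh

        outer, inner = sclera_surfaces
        sa = generate_shell_mesh(outer, inner, N=12, M=10, order=8)
        sb = generate_shell_mesh(outer, inner, N=18, M=15, order=8)
        sens = mesh_sensitivity(sa, sb)
        ua = sens["coarse"]["max_displacement_mm"]
        ub = sens["fine"]["max_displacement_mm"]
        assert sens["displacement_change_pct"] == pytest.approx(abs(ub - ua) / ub * 100)
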