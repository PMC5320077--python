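import numpy as np
import pytest

from harmonichex.harmonic_field import (
    HarmonicConstraints,
    gradient,
    loop_constraints,
    solve_harmonic,
)
from harmonichex.mesh_io import extract_boundary_loops
from harmonichex.surface_tracing import (
    build_surface_grid,
    extract_isocontours,
    match_inner_phase,
    sample_seeds,
    trace_streamline,
)
from harmonichex.synthetic_geometry import make_annulus_fixture


@pytest.fixture(scope="module")
def cylinder_field(cylinder):
    loops = extract_boundary_loops(cylinder)
    z_mean = [cylinder.vertices[lp.vertices][:, 2].mean() for lp in loops]
    top = loops[int(np.argmax(z_mean))]
    bot = loops[int(np.argmin(z_mean))]
    c = HarmonicConstraints(
        np.concatenate([bot.vertices, top.vertices]),
        np.concatenate([np.zeros(len(bot.vertices)), np.ones(len(top.vertices))]),
    )
    f = solve_harmonic(cylinder, c)
    return f, gradient(cylinder, f), top, bot


@pytest.fixture(scope="module")
def annulus_field(annulus):
    f = solve_harmonic(annulus, loop_constraints(annulus))
    return f, gradient(annulus, f)


class TestSampleSeeds:
    def test_four_seeds_on_unit_circle(self):
        surf = make_annulus_fixture(1.0, 2.0, resolution=256)
        loops = extract_boundary_loops(surf)
        seeds = sample_seeds(loops[0], 4, phase=0.0)
        angles = np.degrees(np.arctan2(seeds[:, 1], seeds[:, 0])) % 360
        gaps = np.sort(np.diff(np.sort(angles)))
        assert np.allclose(gaps, 90.0, atol=0.5)

    def test_equal_arc_length_gaps(self, sclera_loops):
        """Brute force: recover each seed's arc-length parameter by walking the polyline."""
        lp = sclera_loops[0]
        N = 17
        seeds = sample_seeds(lp, N)
        closed = np.vstack([lp.points, lp.points[:1]])
        seg = np.diff(closed, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        params = []
        for s in seeds:
            t = np.clip(np.einsum("ij,ij->i", s - closed[:-1], seg) / seg_len**2, 0, 1)
            proj = closed[:-1] + t[:, None] * seg
            k = int(np.argmin(np.linalg.norm(proj - s, axis=1)))
            params.append(lp.arc_length[k] + t[k] * seg_len[k])
        gaps = np.diff(sorted(params))
        assert np.allclose(gaps, lp.total_length / N, rtol=1e-9)

    def test_phase_shift_gives_disjoint_set(self, sclera_loops):
        lp = sclera_loops[0]
        N = 8
        s0 = sample_seeds(lp, N, phase=0.0)
        s1 = sample_seeds(lp, N, phase=lp.total_length / (2 * N))
        d = np.linalg.norm(s0[:, None, :] - s1[None, :, :], axis=2)
        assert d.min() > 0.1  # no shared points

    def test_too_few_seeds_rejected(self, sclera_loops):
        with pytest.raises(ValueError):
            sample_seeds(sclera_loops[0], 2)


class TestTraceStreamline:
    def test_cylinder_vertical_path(self, cylinder, cylinder_field):
        """f linear in height: streamline is a straight vertical line of length H."""
        f, g, top, bot = cylinder_field
        seed = cylinder.vertices[top.vertices[0]]
        sl = trace_streamline(cylinder, f, g, seed, onh_loop=bot)
        assert np.allclose(sl.points[:, 0], seed[0], atol=1e-6)
        assert np.allclose(sl.points[:, 1], seed[1], atol=1e-6)
        length = np.sum(np.linalg.norm(np.diff(sl.points, axis=0), axis=1))
        assert length == pytest.approx(2.0, abs=1e-3)

    def test_annulus_radial_ray(self, annulus, annulus_field):
        """Log-radial field: streamline from the outer rim is a radial ray."""
        f, g = annulus_field
        loops = extract_boundary_loops(annulus)
        seed = np.array([2.0 * np.cos(0.13), 2.0 * np.sin(0.13), 0.0])
        sl = trace_streamline(annulus, f, g, seed, onh_loop=loops[-1])
        # all points collinear with the origin: cross products vanish
        crosses = np.abs(np.cross(sl.points[:-1], sl.points[1:])[:, 2])
        assert crosses.max() < 2e-2  # discrete field bends slightly between rings
        assert np.linalg.norm(sl.points[-1][:2]) == pytest.approx(1.0, abs=0.02)

    def test_values_monotone_decreasing(self, sclera_outer, sclera_field, sclera_loops):
        f, g = sclera_field
        seeds = sample_seeds(sclera_loops[0], 12)
        for seed in seeds:
            sl = trace_streamline(sclera_outer, f, g, seed, onh_loop=sclera_loops[-1])
            assert np.all(np.diff(sl.values) <= 1e-12)
            assert sl.reached_onh

    def test_streamlines_do_not_cross(self, symmetric_surfaces):
        """Brute-force segment intersection between two streamlines (projected)."""
        outer, _ = symmetric_surfaces
        loops = extract_boundary_loops(outer)
        f = solve_harmonic(outer, loop_constraints(outer))
        g = gradient(outer, f)
        seeds = sample_seeds(loops[0], 8)
        a = trace_streamline(outer, f, g, seeds[1], onh_loop=loops[-1])
        b = trace_streamline(outer, f, g, seeds[2], onh_loop=loops[-1])

        def seg_intersect_2d(p1, p2, q1, q2):
            d1, d2 = p2 - p1, q2 - q1
            den = d1[0] * d2[1] - d1[1] * d2[0]
            if abs(den) < 1e-14:
                return False
            t = ((q1[0] - p1[0]) * d2[1] - (q1[1] - p1[1]) * d2[0]) / den
            s = ((q1[0] - p1[0]) * d1[1] - (q1[1] - p1[1]) * d1[0]) / den
            return 1e-9 < t < 1 - 1e-9 and 1e-9 < s < 1 - 1e-9

        pa = a.points[:, :2]
        pb = b.points[:, :2]
        hits = sum(
            seg_intersect_2d(pa[i], pa[i + 1], pb[j], pb[j + 1])
            for i in range(len(pa) - 1)
            for j in range(len(pb) - 1)
        )
        assert hits == 0


class TestIsoContours:
    def test_cylinder_midheight_circle(self, cylinder, cylinder_field):
        f, g, top, bot = cylinder_field
        (contour,) = extract_isocontours(cylinder, f, [0.5], grad=g)
        assert np.allclose(contour.points[:, 2], 1.0, atol=1e-9)
        assert contour.length == pytest.approx(2 * np.pi, rel=0.01)

    def test_level_equal_to_vertex_value_still_closed(self, cylinder, cylinder_field):
        f, g, top, bot = cylinder_field
        vertex_level = float(f[np.argmin(np.abs(f - 0.5))])
        (contour,) = extract_isocontours(cylinder, f, [vertex_level], grad=g)
        gap = np.linalg.norm(contour.points[0] - contour.points[-1])
        assert gap < 0.3  # closed polyline (last segment implied)
        assert len(contour.points) >= 40

    def test_contours_pairwise_disjoint(self, sclera_outer, sclera_field):
        f, g = sclera_field
        levels = np.linspace(0.2, 0.8, 5)
        contours = extract_isocontours(sclera_outer, f, levels, grad=g)
        assert len(contours) == 5
        for i in range(len(contours)):
            for j in range(i + 1, len(contours)):
                d = np.linalg.norm(
                    contours[i].points[:, None, :] - contours[j].points[None, :, :], axis=2
                )
                assert d.min() > 1e-3

    def test_interpolated_values_at_level(self, sclera_outer, sclera_field):
        f, g = sclera_field
        (contour,) = extract_isocontours(sclera_outer, f, [0.37], grad=g)
        # verify each point reproduces the level via barycentric interpolation
        from harmonichex.mesh_io import closest_point_on_surface

        import trimesh.triangles as tt

        tris = sclera_outer.vertices[sclera_outer.triangles[contour.triangles]]
        bary = tt.points_to_barycentric(tris, contour.points)
        vals = np.sum(bary * f[sclera_outer.triangles[contour.triangles]], axis=1)
        assert np.max(np.abs(vals - 0.37)) < 1e-9


class TestSurfaceGrid:
    def test_cylinder_grid_regular(self, cylinder, cylinder_field):
        f, g, top, bot = cylinder_field
        N, M = 8, 5
        seeds = sample_seeds(top, N)
        levels = 1.0 - np.arange(M) / (M - 1)
        lines = [trace_streamline(cylinder, f, g, s, onh_loop=bot) for s in seeds]
        grid = build_surface_grid(lines, levels, top, bot)
        # rows at equal heights, columns at equal angles
        for j in range(M):
            assert np.allclose(grid.nodes[:, j, 2], 2.0 * levels[j], atol=1e-6)
        ang = np.degrees(np.arctan2(grid.nodes[:, 2, 1], grid.nodes[:, 2, 0]))
        gaps = np.sort((np.diff(np.sort(ang)) + 360) % 360)
        assert np.allclose(gaps, 45.0, atol=1e-3)

    def test_grid_nodes_on_surface(self, small_shell):
        """Corner nodes lie on the source surfaces to ~1e-9 (the on-model guarantee)."""
        from harmonichex.mesh_io import closest_point_on_surface

        mesh = small_shell.mesh
        for name, surf in [("on_outer_surface", small_shell.outer), ("on_inner_surface", small_shell.inner)]:
            ids = mesh.node_sets[name]
            _, d, _ = closest_point_on_surface(surf, mesh.nodes[ids])
            assert d.max() < 1e-9

    def test_streamline_contour_near_orthogonality(self, sclera_outer, sclera_field, sclera_loops):
        """Angle between streamline direction and contour tangent is 90 +- 15 deg."""
        f, g = sclera_field
        seeds = sample_seeds(sclera_loops[0], 10)
        (contour,) = extract_isocontours(sclera_outer, f, [0.5], grad=g)
        for seed in seeds[:4]:
            sl = trace_streamline(sclera_outer, f, g, seed, onh_loop=sclera_loops[-1])
            p = sl.point_at_level(0.5)
            k = int(np.argmin(np.abs(sl.values - 0.5)))
            k = max(1, min(k, len(sl.points) - 1))
            t_stream = sl.points[k] - sl.points[k - 1]
            j = int(np.argmin(np.linalg.norm(contour.points - p, axis=1)))
            t_cont = contour.points[(j + 1) % len(contour.points)] - contour.points[j]
            cosang = np.dot(t_stream, t_cont) / (np.linalg.norm(t_stream) * np.linalg.norm(t_cont))
            angle = np.degrees(np.arccos(np.clip(abs(cosang), 0, 1)))
            assert 75.0 <= angle + 1e-9  # |90 - angle_between| <= 15

    def test_quads_are_simple(self, small_shell):
        """Every surface quad of the outer grid is non-self-intersecting."""
        nodes = small_shell.grid_outer.nodes
        N, M = nodes.shape[:2]
        for i in range(N):
            for j in range(M - 1):
                quad = np.array(
                    [nodes[i, j], nodes[(i + 1) % N, j], nodes[(i + 1) % N, j + 1], nodes[i, j + 1]]
                )
                # project onto best-fit plane and check winding consistency
                c = quad.mean(axis=0)
                q = quad - c
                _, _, vt = np.linalg.svd(q)
                uv = q @ vt[:2].T
                a = np.roll(uv, -1, axis=0) - uv
                b = np.roll(uv, -2, axis=0) - np.roll(uv, -1, axis=0)
                cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
                assert np.all(cross > 0) or np.all(cross < 0)


def test_match_inner_phase_aligns_seed_rings(sclera_surfaces):
    from harmonichex.mesh_io import extract_boundary_loops

    outer, inner = sclera_surfaces
    lo = extract_boundary_loops(outer)[0]
    li = extract_boundary_loops(inner)[0]
    outer_seeds = sample_seeds(lo, 16)
    phase = match_inner_phase(outer_seeds, li)
    inner_seeds = sample_seeds(li, 16, phase=phase)
    d = np.linalg.norm(inner_seeds - outer_seeds, axis=1)
    # matched points should be separated by roughly the wall thickness (0.38 mm)
    assert d.max() < 0.6
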