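import numpy as np
import pytest

from harmonichex.harmonic_field import gradient, loop_constraints, solve_harmonic
from harmonichex.hex_mesher import generate_shell_mesh
from harmonichex.mesh_io import extract_boundary_loops
from harmonichex.synthetic_geometry import (
    ScleraFixtureSpec,
    make_annulus_fixture,
    make_cylinder_fixture,
    make_sclera_fixture,
)


@pytest.fixture(scope="session")
def sclera_surfaces():
    """Default synthetic sclera shell: (outer, inner) surfaces."""
    return make_sclera_fixture(ScleraFixtureSpec())


@pytest.fixture(scope="session")
def sclera_outer(sclera_surfaces):
    return sclera_surfaces[0]


@pytest.fixture(scope="session")
def sclera_field(sclera_outer):
    """Solved harmonic field and per-triangle gradient on the outer surface."""
    f = solve_harmonic(sclera_outer, loop_constraints(sclera_outer))
    return f, gradient(sclera_outer, f)


@pytest.fixture(scope="session")
def sclera_loops(sclera_outer):
    return extract_boundary_loops(sclera_outer)


@pytest.fixture(scope="session")
def symmetric_surfaces():
    """Rotationally symmetric variant: canal centred on the pole, no jitter."""
    return make_sclera_fixture(ScleraFixtureSpec(canal_offset_deg=0.0, jitter=0.0))


@pytest.fixture(scope="session")
def small_shell(sclera_surfaces):
    """Moderate-resolution meshed shell shared by frame/region/FE tests."""
    outer, inner = sclera_surfaces
    return generate_shell_mesh(outer, inner, N=24, M=18, order=20)


@pytest.fixture(scope="session")
def annulus():
    return make_annulus_fixture(1.0, 2.0, resolution=96)


@pytest.fixture(scope="session")
def cylinder():
    return make_cylinder_fixture(radius=1.0, height=2.0, n_circ=48, n_axial=24)
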