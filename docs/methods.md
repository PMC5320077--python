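# Methods

`harmonichex` builds patient-specific hexahedral finite-element models of the
posterior sclera — the stiff collagenous shell of the eyeball — from a pair of
triangulated surfaces (outer and inner shell wall), and solves the linear
orthotropic elasticity problem of that shell inflated by intraocular pressure
(IOP). This note records the models, the numerical choices, and what the
synthetic test geometry does and does not establish.

## Harmonic scalar field

Both input surfaces are open annular surfaces with two boundary rings: the
equator ring and the optic-nerve-head (ONH) canal ring. On each surface we
solve the discrete Laplace equation `(L f)_i = 0` at every interior vertex,
with the cotangent ("discrete harmonic") edge weights

    w_ij = (cot a_ij + cot b_ij) / 2,

where `a_ij`, `b_ij` are the angles opposite edge `(i, j)` in its one or two
incident triangles (boundary edges use the single available cotangent).
Dirichlet values pin the field to 0 on the ONH ring and 1 on the equator ring;
any affine rescale is equivalent, so the canonical [0, 1] range is fixed once.
Eliminating constrained rows/columns leaves a symmetric positive-definite
system solved directly (sparse LU) below 50 000 unknowns and by
Jacobi-preconditioned conjugate gradients (relative tolerance 1e-10) above.
Negative weights from obtuse triangles are kept, not clamped — clamping would
change the operator — and their count is reported on the operator; with
nonnegative weights the solution obeys the discrete maximum principle
(extrema only at the rings), which the tests assert.

## Streamlines, isocontours, and the surface grid

The field's gradient is constant inside each triangle, so streamlines of
`-grad f` are exact polylines: a straight segment inside each triangle joined
at exact edge crossings — no ODE integrator and no step-size parameter.
`N` seeds are placed at equal arc length around the equator ring and traced to
the canal. Two degenerate situations require care and are resolved
deterministically:

- **Edge-pinned flow.** When the descent direction is tangential to the edge
  the point lies on (the rotationally symmetric fixture produces exactly this
  along mesh meridians), the tracer first tests whether the neighbouring
  triangle carries the flow onward into its interior (a consistent crossing);
  only if it does not, the motion is constrained to the edge and slides toward
  decreasing `f`.
- **Vertex fans.** At a vertex where the constrained direction also vanishes,
  the tracer hops across the steepest descending incident edge at zero cost
  until a triangle accepts the flow. Vertex hits during tracing and
  contouring are perturbed by 1e-12 toward the interior.

Isocontours at `M` evenly spaced field values (even spacing in scalar value;
an arc-length option exists but is off by default) are extracted by marching
over triangles with linear edge interpolation and stitched into closed rings,
oriented along `grad f x n` so their tangent matches the circumferential
material axis. Grid node `(i, j)` is the point on streamline `i` with
`f = level_j`, found by monotone interpolation along the streamline samples;
rows 0 and `M-1` are the on-ring seed and snap points themselves, so the mesh
boundary lies exactly on the input boundary. Inner-surface seeds reuse the
outer seeds' normalized arc-length parameters with a phase chosen (dense 1-D
search plus bounded refinement) to minimize the summed distance to the outer
seeds, making the two grids share topology.

## Hexahedral assembly and quality

The outer and inner `N x M` grids are joined through interpolated interior
node layers (default: one middle layer, i.e. two element layers, so
`N*(M-1)*2` hexahedra). Conversion to 20-node serendipity elements adds one
shared mid-edge node per unique edge; mid-nodes of edges lying in the outer
(inner) surface are projected to the closest point of that triangulation, and
mid-nodes on the equator/ONH rings are projected onto the ring polyline itself
so the boundary stays on the boundary. All other mid-nodes are exact segment
midpoints.

Quality is reported as per-edge dihedral-angle distortion: for each of the 12
edges of a hexahedron, the interior angle between its two adjacent bilinear
faces is evaluated from outward face normals at the shared edge midpoint;
distortion is `|angle - 90 deg|`. This estimator scores a perfect cube exactly
zero and a cube sheared by 20 degrees exactly 20 on the four affected edges.
Distortions are aggregated into 10-degree bins plus mean and maximum. Element
validity uses the corner scaled Jacobian of the trilinear corner shape
(hard error at <= 0, warning threshold 0.2).

## Material frames, regions, and rotation schemes

Each element's centroid is projected to the outer surface; the local frame is
y = normalized field gradient (meridional fibres), z = surface normal signed
to point outward through the shell, x = y cross z (circumferential fibres,
tangent to the isocontours). Elements are labelled by the field value `u` at
the projection: `u < u1` ONH-adjacent, `u < u2` peripapillary, else
peripheral, with defaults `u1 = 0.15`, `u2 = 0.45` (the bands are
isocontour-aligned rings; the literature names these regions without
quantifying them, so the thresholds are configurable).

The fibre-rotation comparison models rotate x and y about z region by region.
Model `rk` uses peripapillary `min((k-1)*10, 80)` degrees and peripheral
`min(k*10, 90)` degrees; the cap at the quarter turn is the only rule
consistent with all four printed models (r1 peripheral 10; r2 10/20; r3
20/30; r10 80/90) and keeps angles within [0, 90] degrees — a consequence is
that r9 and r10 coincide. The ONH-adjacent band rotates with the
peripapillary angle.

Orthotropic constants default to the scleral set `E_x = 8.6`, `E_y = 6`,
`E_z = 2.5` MPa with a single Poisson ratio 0.49 applied as
`nu_xy = nu_yz = nu_xz` (reciprocals from compliance symmetry); shear moduli
are not reported for sclera, so the closure `G_ij = sqrt(E_i E_j) / (2(1+nu))`
is used — it reduces exactly to the isotropic shear modulus when the moduli
coincide and keeps the stiffness positive definite for the scleral constants
(verified at construction). The isotropic comparison model uses
`E = 3.8` MPa, `nu = 0.49`. Stiffnesses are rotated to global coordinates by
the full fourth-order tensor transformation.

## Finite elements

The solver is geometrically and materially linear. The source data motivates
20-node elements by large deformation, but every comparative conclusion the
package reproduces is an ordering or a location, reproducible in the
small-strain regime; nonlinearity is declared out of scope rather than
approximated silently. Consequences: pressure loads use undeformed normals
(no follower-load stiffness) and reported displacements at 30 mmHg are small
(tens of micrometres on the synthetic shell).

- 20-node serendipity elements, full 3x3x3 Gauss quadrature.
- 8-node elements use 2x2x2 quadrature with a mean-dilatation (B-bar)
  volumetric treatment to avoid locking at nu = 0.49.
- Consistent nodal pressure forces on (serendipity) quad faces, 3x3 Gauss per
  face, outward orientation determined per face against the element centroid.
- mmHg are converted at the boundary with 1 mmHg = 133.3224e-6 MPa.
- Direct sparse LU on the reduced system; deterministic ordering, so repeated
  runs are bit-stable on one platform.
- Verification: single-element patch tests (8- and 20-node, orthotropic) are
  exact to 1e-9; the Lame thick-walled-sphere benchmark on a mapped spherical
  octant converges monotonically to <2% radial-displacement error; a
  transversely isotropic thick sphere agrees with an independent 1-D
  boundary-value-problem solution; global equilibrium holds to 1e-8 on every
  solve.

The Lame benchmark mesh covers one octant of a thick spherical shell by three
bilinear quad patches (corners -> edge midpoints -> face centre of the
spherical triangle) swept radially — a single (theta, phi) mapped patch would
degenerate at the pole — with symmetry planes as node sets and the spherical
walls as face sets.

## Synthetic geometry: what it emulates and what it does not

No scan is distributed, so all tests run on a generated fixture: the
posterior hemisphere of a 12 mm sphere with a geodesic canal hole of radius
1.75 mm whose centre is tilted 15 degrees from the pole, and wall thickness
`t(theta) = t_eq + (t_pole - t_eq) cos^2(theta)` interpolating 1.1 mm at the
pole and 0.38 mm at the equator (cosine interpolation in polar angle; the
endpoints are measured scleral values, the blend is a package choice with
zero slope at both ends). `R = 12` mm and the canal radius are fixture
choices consistent with adult eye anatomy, not measured values. Optional
seeded tangential jitter breaks the rotational symmetry; with offset 0 and
jitter 0 every downstream quantity is rotationally symmetric to ~1e-6, a
strong end-to-end smoke test.

The fixture is smoother and more symmetric than a scanned sclera: it has no
azimuthal thickness variation, and its equator ring is *uniformly* at the
minimum thickness. Two consequences matter when reading the comparison
study:

- The clamped, uniformly thin equator develops a bending boundary layer; the
  global maximum principal stress sits in elements adjacent to the clamp and
  sharpens under refinement (3.8% change between the default and
  1.5x-refined meshes, versus 0.6-0.7% convergence of the band maxima away
  from the clamp), and the isotropic model bulges most just inside the clamp.
  On scanned geometry with azimuthally varying thickness the global extrema
  need not sit at the clamp; on this fixture they do.
- Away from the clamp the expected orderings hold: the perfect-anisotropic
  model's maximum displacement is in the ONH-adjacent band, the isotropic
  model displaces less than the anisotropic one near the ONH, and the
  isotropic principal strain exceeds the anisotropic one in every band.

Passing tests on the fixture therefore establish the correctness of the
pipeline (meshing, frames, assembly, solution, postprocessing) and the
orderings local to the ONH; they do not establish clamp-adjacent behaviour of
real scleras.

## Default problem sizes

The default mesher resolution N = 40, M = 34 with two element layers gives
2 640 twenty-node hexahedra (~44 000 dof), solving in tens of seconds on one
core; the 12-model comparison study reuses one mesh and runs in a few
minutes. The mesh-sensitivity pair refines to N = 60, M = 51 (6 000
elements, ~100 000 dof). The surface fixture default is 96 x 48 vertices per
surface, chosen so the default hex mesh is comparable in element count to a
typical patient-specific shell model.

## Known limitations

- Small-strain linearity (no hyperelasticity, viscoelasticity, or follower
  pressure); magnitudes are not comparable to large-deformation solutions,
  only locations and orderings.
- The ONH plug tissue is not meshed; the canal ring is a free edge, and the
  "ONH region" maxima refer to the sclera adjacent to the canal.
- Streamline tracing assumes the two-ring annular topology (no interior
  extrema); surfaces with more boundary loops or handles are rejected.
- The region thresholds u1/u2 and the shear-modulus closure are conventions,
  configurable but not data-derived.
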