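# Methods

This document describes the model implemented by `osteorom`, the
assumptions behind it, the meaning and defaults of its parameters, what
the synthetic joint generator emulates, the numerical choices made, and
the known limitations. Quantitative claims below are restricted to
properties the test suite actually computes.

## 1. The model

**Osteological ROM.** The range of motion of a ball-and-socket joint is
modelled as the set of rotation triples (FE, ABAD, LAR) — flexion–
extension, abduction–adduction, long-axis rotation — at which the posed
head-bearing bone does not interpenetrate the socket-bearing bone. Both
bones are rigid triangle meshes; soft tissue is not modelled except as
an optional uniform joint-spacing allowance (below). Surface contact
with zero penetration volume counts as *viable*: the constraint is
interpenetration, not proximity.

**Joint centre.** The pivot is derived from geometric primitives fitted
to the articular surface patches by least squares:

- *sphere* — linear least squares on the expanded sphere equation;
- *ellipsoid* — an algebraic stage (a constrained quadric fit
  guaranteeing an ellipsoid solution) followed by geometric
  (point-to-surface) refinement;
- *cylinder* and *plane* — for hinge-like surfaces and facets.

The default `socket_pivot` rule places the rotation centre at the
socket-fit centre and pins the head-fit centre to it at the reference
pose; a `head_pivot` rule swaps the roles. If one of the two fits is a
plane (no centre), the other centre is used.

**Joint coordinate system.** Proximal and distal anatomical frames must
coincide at the reference pose (enforced, not silently re-zeroed).
Rotations follow the intrinsic FE → ABAD → LAR convention common in
XROMM-style joint kinematics: FE about the proximal z axis, ABAD about
the floating mutual perpendicular (y after FE), LAR about the distal x
axis, all right-handed; the world rotation is `P · Rz(fe) · Ry(abad) ·
Rx(lar) · Pᵀ` with `P` the proximal axis matrix. At |ABAD| = 90° the FE
and LAR axes align (gimbal lock); the inverse mapping flags this and
reports LAR = 0 there. A finite-helical-axis routine decomposes the
relative motion between two placements into an axis, a rotation angle
and an advance; relative rotations under 1° are rejected as numerically
unstable rather than returned with garbage axes.

**Cartilage allowance.** Epiphyseal cartilage, absent in dry or fossil
bone, is modelled as a pure translation of the femur along the socket
pole axis (out of the cup) by `pct × femur_length`, applied after the
rotation. This is the standard "joint spacing as a percentage of femur
length" sensitivity treatment: it widens the joint uniformly without
changing the rotation convention. It is a deliberate simplification —
real cartilage is neither uniform nor a rigid offset.

**Pose lattice.** The default grid covers FE ∈ [−180°, 180°],
ABAD ∈ [−90°, 90°], LAR ∈ [−180°, 180°] at a 5° step: 73 × 37 × 73 =
197,173 cells. The ±180° samples of FE and LAR are the same physical
pose sampled twice; downstream connectivity offers two seam policies,
`endpoints-distinct` (treat them as separate cells) and `seam-merged`
(identify them). ABAD is never periodic.

## 2. Collision detection

Two independent formulations decide whether a posed triangle mesh
interpenetrates another:

- **Production path (`bvh`).** A vectorised axis-aligned bounding-box
  broad phase over all triangle pairs, then an exact interval
  (Möller-style) narrow phase: two triangles overlap iff each strictly
  straddles the other's plane (vertices beyond tolerance on *both*
  sides) and their spans on the plane–plane intersection line overlap
  by more than tolerance. Touching triangles, shared edges and coplanar
  contact therefore do **not** count — they have zero penetration
  volume.
- **Oracle path (`brute`).** An all-pairs edge-piercing test: the
  meshes overlap if some triangle edge strictly pierces the interior of
  a triangle of the other mesh. This formulation shares no code or
  geometry with the interval test and serves as its independent check.
  One degeneracy is handled explicitly: with congruent tessellations,
  every edge–plane crossing point of a genuinely crossing pair can land
  exactly on the other triangle's boundary. Pairs with ≥ 2
  boundary-grade crossing points and no strict hit are re-examined by
  testing midpoints of crossing-point pairs for strict interiority in
  both triangles.

Full containment (one mesh swallowed by the other, no surface crossing)
is detected by a ray-parity test on a representative vertex; for
non-watertight input this check is skipped with a warning and detection
degrades to surface-intersection-only mode.

**Sweep culling.** Every pose rotates the femur about the fixed joint
centre, so a femur triangle whose maximum distance from the pivot (plus
the cartilage offset length) is below the socket's minimum distance
from the pivot can never collide at any pose. Those triangles are
culled once before the sweep; the per-cell verdict is provably
unchanged (the cull criterion is a distance bound, not a heuristic),
and a unit test compares swept verdicts against per-cell direct calls.

## 3. ROM metrics

**Volumes.** Two definitions are always reported. The *naive* volume
assigns step³ degrees³ per viable cell — exact bookkeeping of lattice
cells, directly comparable across runs at the same step. An Euler grid,
however, oversamples orientations near |ABAD| → 90° (a 5° × 5° patch of
(FE, LAR) near the pole spans far less solid angle than at the
equator), so the *cosine-corrected* volume weights each cell by
cos(ABAD) and is the default headline number. The cosine volume is
never larger than the naive volume, and cells exactly at |ABAD| = 90°
contribute nothing to it.

**Connectivity and locking.** Connected components of the viable set
use 6-neighbour (face) connectivity, with the FE/LAR seams optionally
identified (`seam-merged`). The locking report examines each ABAD slice
of the lattice as a 2-D (FE, LAR) map with LAR always periodic: a slice
with ≥ 2 components is *locked* (disconnected pose clusters that cannot
be traversed without interpenetration), and a slice is *free* when it
is one component and some FE row admits an unbroken 360° LAR circuit.

**Extreme poses.** The viable pose maximising or minimising one angle
under closed-interval constraints on the others, with deterministic tie
breaking (smallest |LAR|, then smallest |FE|, then signed values).

**Joint spacing.** The mean signed clearance from the head patch to the
socket patch, signed negative where the head surface lies outside the
socket surface relative to the socket-fit centre (interpenetration).
The spacing report crosses primitive pairings {S, E} × {S, E} with
cartilage percentages and tags each row with the naming-scheme label
(for example `DEMO SE0`).

## 4. The synthetic joint generator

The generator produces watertight, validated socket and femur meshes
with exact ground truth, emulating — at the level of gross geometry,
with no claim of anatomical fidelity — a well-preserved archosauriform
hip: a deep acetabular cup with a dorsal supra-acetabular rim lip, and
a femur with an offset, mildly ellipsoidal head on an angled neck.

Socket parameters (`SocketSpec`, mm/degrees):

| parameter | default | why |
|---|---|---|
| `cup_radius` | 6.0 | small-archosauriform scale; sets the mm scale of the whole scene |
| `depth_fraction` | 1.0 | full hemisphere (opening at polar 90°), so the rim lip is the *only* feature past the equator |
| `rim_overhang_deg` | 25.0 | lip extends 25° past the opening; large enough to engage the femoral neck at strong abduction |
| `rim_arc_deg` | 12.0 | azimuthal plateau width of the lip; narrow enough that swinging FE can escape it |
| `rim_taper_deg` | 3.0 | lip ends taper over 3° rather than a step, keeping the mesh clean |
| `rim_azimuth_deg` | 270.0 | lip centred dorsally (−z at reference) |
| `shell_thickness` | 1.5 | gives the cup a closed outer wall (watertightness) |
| `mesh_resolution` | 3 | 16·res azimuthal samples; see §5 |

Femur parameters (`FemurSpec`): `head_radii` (5.4, 5.1, 4.9) — mildly
triaxial so the ellipsoid fit is distinguishable from the sphere fit
while still nesting in the cup; `neck_length` 10; `neck_angle_deg` 130
(shaft deviates from the neck axis as in an offset femoral head);
`shaft_length` 45; `shaft_radius` 1.0 — thin enough that the neck tube
subtends a small angle at the pivot (below). Vertex noise
(`noise_sigma_mm`) is seeded and optional; with zero noise the
generator is bit-deterministic and the seed is ignored.

**Angular-clearance design of the demo.** The demo's locking behaviour
is built analytically, not tuned. At pose (FE, ABAD) the neck direction
makes polar angle p = arccos(cos FE · cos ABAD) with the cup pole, and
the neck tube of radius ρ at band radius r subtends a half-width
ε = atan(ρ / r). The lip occupies polar angles up to
`opening + rim_overhang` in an azimuthal arc of half-width
(12 + 2·3)/2 = 9° around 270°. With the defaults, a pose at ABAD = +60°,
FE ≈ 0 puts the neck inside the lip's angular shadow (locked pockets on
either side in FE), while |FE| ≳ 45° swings the neck azimuthally past
the lip (escape), and all adducted poses point away from the lip
entirely. Two properties follow by construction and are asserted in
tests:

- *Rim monotonicity.* Growing `rim_overhang_deg` only adds lip
  vertices outward; the cup-proper vertex lattice is identical across
  overhang values (verified by a nesting test). A pose colliding with a
  smaller lip therefore collides with every larger one, and viable
  counts are non-increasing in overhang.
- *LAR-independence.* In the demo scene, collisions involve only the
  neck tube and head against the cup and lip. The shaft and the
  neck–shaft blend never reach into the radial band where the socket
  lives, and the head is a surface of revolution about the neck axis to
  within its small triaxiality; viability in the demo is therefore
  (near-)independent of LAR, which is why locked slices still show full
  LAR circuits within each pocket. Locking in the demo is an
  (FE, ABAD) phenomenon, as intended.

## 5. Numerical choices

- **Mesh resolutions.** Acceptance-level demo sweeps use
  `mesh_resolution=2`; the viable lattice and locking structure were
  verified to be *identical* at resolution 3 before 2 was adopted (the
  15° lattice summary matches cell for cell), so the cheaper meshes
  change nothing but runtime. Oracle-agreement tests use resolution 1
  (≤ 500 triangles per bone) to keep the all-pairs brute force
  tractable. Spacing against the closed form uses resolution 4, because
  chord sag of coarse facets biases mean clearance measurably at lower
  resolutions.
- **Strict-straddle overlap.** Both narrow-phase predicates are strict:
  contact, shared edges and coplanar pairs are non-overlaps. The
  tolerance is relative to the magnitudes involved.
- **Rotation-angle conditioning.** Frame-coincidence angles are
  computed with atan2 of the rotation's skew norm against
  (trace − 1)/2, which is well-conditioned near the identity, instead
  of arccos of the trace, which is not.
- **Ellipsoid fit fallback.** The constrained algebraic ellipsoid stage
  is degenerate for exactly spherical data; in that case the geometric
  refinement is seeded from a sphere fit (equal semi-axes, identity
  axes) instead of failing.
- **Determinism.** No compute stage consults a random source; the only
  randomness in the package is the generator's optional seeded vertex
  noise. Sweeps, metrics and serialisations are bit-reproducible, and
  grid files round-trip exactly (bit-packed lattice plus JSON header).

## 6. Limitations

- The joint model has three rotational degrees of freedom about a fixed
  centre plus the cartilage translation; physiological translations
  (e.g. femoral head sliding within the acetabulum) are not searched.
- Osteological ROM is an *outer bound* on life posture: ligaments,
  musculature and articular cartilage geometry all restrict real motion
  further, and none are modelled.
- Euler-grid cells are not equal solid-angle cells; the cosine volume
  corrects the first-order distortion but results remain convention-
  dependent (FE → ABAD → LAR order, axis assignment).
- Mean spacing is a facet-level estimate; very coarse meshes bias it
  (chord sag), which is why closed-form comparisons use finer meshes.
- Exactly coincident surfaces (two identical meshes in the same pose)
  are reported as non-intersecting: every triangle pair is contact- or
  coplanar-grade and the containment probe point lies on the boundary,
  where ray parity is undefined. This configuration is measure-zero and
  unreachable from generic poses.
- Non-watertight input degrades collision detection to
  surface-intersection-only mode (containment cannot be tested); this
  is warned about, not repaired.
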