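# Methods

This note documents the models inside `craniostrain`: what is simulated,
which parameters matter, the numerical choices, and what the synthetic
phantom can and cannot say about real crania.

## Coordinate frame and units

Mediolateral = +x (mid-sagittal plane at x = 0), anteroposterior = +y
(anterior positive), dorsoventral = +z (dorsal positive). Lengths in mm,
forces in N, moduli in MPa, strains reported in microstrain (µε). Moments
are N·mm. Element and node indices are 0-based internally; the Abaqus INP
export is 1-based, per that format's convention.

## The cranium phantom

The phantom is a labelled voxel geometry meshed with six Kuhn tetrahedra
per voxel. It is generated on the x ≥ 0 half and mirrored, so the mesh is
exactly mirror-symmetric: element `i` and element `i + n/2` are geometric
mirror images with identical material labels. This is what makes the
mirror-equivalence checks of the pipeline exact (left-bite strain fields
equal the mirrored right-bite fields to solver precision) rather than
approximate.

Default geometry (all configurable through `PhantomParams`):

| parameter | default | meaning |
|---|---|---|
| width × height | 24 × 16 mm | outer shell cross-section |
| length | derived | `incisor_y + 7`; 56 mm with 5 cheek teeth |
| shell thickness | 2 mm | roof, floor (palate), four walls |
| cell size | 1 mm | voxel edge = element size |
| tooth row | 1 incisor + 5 cheek teeth per side | pegs through the palate |
| PDL ring | 2 mm | ≥ 2 elements through-thickness, enforced |
| suture seam | 2 mm wide | crosses the full roof mediolaterally |
| fenestration | 4 struts × 2 mm | lateral wall window, anterior region |
| tooth length | 4 mm | exposed crown below the palate |

Each tooth peg is a 3 × 3 mm column (1 mm² pulp core inside a 1 mm tooth
wall) seated in a socket whose lining is PDL on all lateral sides, so no
tooth element ever shares a face with bone — every load path from tooth to
socket crosses the compliant ligament, as in a real periodontium. Teeth
below the palate are free-standing (crown in air). The thin-layer rule
(PDL and suture at least two elements through-thickness) mirrors standard
practice for meshing compliant layers; `PhantomParams.validate` rejects
configurations that violate it.

Landmark node sets: `tmj_left/right` on the ventral posterior surface,
`tooth_tip:<id>` at each tooth tip, `origin:<strand id>` for all 130
muscle strand origins, and `midsagittal_plane`. The jaw model is built
from the same layout function, so landmarks and strand attachments can
never drift apart.

The phantom deliberately omits: curved anatomical surfaces, a braincase
distinct from the rostrum, tooth roots with sockets deeper than the
palate, orbital structures. It exists to exercise every material type,
the fenestration concept and symmetry — conclusions about real crania
require real geometry.

## Jaw model and bite cycles

The mandible is rigid, suspended at two TMJ points. Two generalized
coordinates describe its motion: gape θ (rotation about the mediolateral
axis through both TMJs) and working-side excursion φ (rotation about the
anteroposterior axis through the working-side TMJ — the balancing condyle
translates). A bite cycle prescribes θ(t), φ(t) through three phases
(defaults: opening 0.085 s, fast close 0.065 s, slow close 0.100 s,
Δt = 5 ms, a ≈ 0.25 s cycle):

* opening: cosine ramp of θ from 0 to the maximal gape (default 12°);
* fast close: θ returns to the food-contact gape (default 2°) while φ
  ramps to the working-side excursion (default 5.5°, molar only);
* slow close: the bolus is processed — θ → 0 linearly (compression
  fraction c = 1 at full closure) while φ returns to the midline.

The bolus resists vertically with `R_v · c` (R_v = 30 N — "compressed
completely" at c = 1) and mediolaterally with `R_ml · c` (R_ml = 30 N)
while the jaw is still deflected toward the working side. Transmitting the
mediolateral resistance in proportion to the vertical engagement is a
modelling choice: a bolus carrying no normal force cannot transmit shear,
and without this coupling the activation problem is ill-posed at
slow-close onset (a finite side force with zero bite force would demand a
jaw-opener moment the masticatory muscles cannot produce). Bite force is
the occlusal (vertical) component, so its maximum — the FE snapshot
instant — falls at full closure, with the jaw back at the midline.

Incisor cycles use the same gape but zero excursion and no mediolateral
resistance; the task is mirror-symmetric and the optimizer returns exactly
mirror-equal activations.

### Muscle strands

65 strands per side in five groups (masseter 20, zygomaticomandibularis
10, temporalis 20, medial pterygoid 10, lateral pterygoid 5). Origins sit
on phantom landmark nodes; superficial-temporalis strands wrap over the
lateral roof edge and down the outer wall via fixed via points, and the
lateral pterygoid wraps along the ventral surface — both become truss
chains in the FE model. Per-strand maximum isometric forces (masseter 6 N,
zygomaticomandibularis 3 N, temporalis 2.5 N, medial pterygoid 5 N,
lateral pterygoid 2 N) are synthetic values sized so group totals follow
the usual masticatory hierarchy; absolute bite-force magnitudes of the
phantom are therefore not comparable to any real species.

Passive tension: `T(s) = 0.001 · F_max · expm1(k·s)/expm1(k·s_max)` for
strand strain `s = (L−L0)/L0`, with k = 3, s_max = 0.05, clipped at the
cap — zero at slack, monotone, saturating at 0.1 % of F_max. Slack length
is the closed-pose strand length. Passive tension is added to every
transmitted strand force but excluded from the activation balance: it is
three orders of magnitude below active forces, and the strand set contains
no jaw openers to cancel its closing moment during opening. At the FE
snapshot the jaw is closed and passive tension is exactly zero, so the
snapshot force balance is unaffected.

### Activation optimization

At each time step the required generalized forces along the mobile
directions are the projections of the external wrench (bolus resistances,
optional gravity, optional inertia from finite-differenced rigid-body
accelerations; quasi-static is the default since chewing is slow and only
the maximum-bite-force snapshot feeds the FE stage). The activation QP —
minimize Σ(a_i/w_i)² subject to the generalized balance and 0 ≤ a ≤ 1 —
is solved by an active-set method exploiting the diagonal Hessian, after a
bounded-least-squares feasibility check that reports *which* generalized
component is unreachable when capacity is insufficient. EMG weights are
per-group trapezoid-style stand-ins (working side 1.0 vs balancing 0.6 for
the closers during molar slow close; the working-side medial pterygoid
drives the return to the midline; floor weight 0.05), config-editable.

TMJ reactions are recovered per time step by least squares over the two
joint point forces; the six balance equations have rank five (no moment
about the inter-TMJ axis is producible by the joints — that component is
exactly what the gape equation of the QP closes), so the recovery is exact
at the snapshot.

## Finite elements

Standard displacement-based tetrahedra: 4-node (constant strain, centroid
recovery) and 10-node (4-point Gauss rule, volume-averaged recovery;
midside nodes at true edge midpoints since the phantom is piecewise
planar). Isotropic linear elasticity per material; defaults: bone
13 700 MPa/0.3, tooth (dentine and enamel merged) 19 890 MPa/0.31, PDL
50 MPa/0.49, suture 20 MPa/0.49, pulp 2 MPa/0.49, links = bone. Sparse
direct solve (SuperLU); a near-zero pivot raises an explicit
singular-system error. Verified by: exact patch test at both orders,
assembly against an independent dense finite-difference oracle, cantilever
convergence to the Euler–Bernoulli tip deflection (monotone, < 5 % at the
finest level tested), bimaterial series-bar strain ratios, global
equilibrium of reactions in every solve, and linearity/superposition.

Muscle wrapping paths become chains of axial truss elements (1 mm² section,
bone stiffness, so they transfer force with minimal deformation). Path
points coinciding with surface nodes reuse them; floating joints get a new
node tied to the nearest surface node by a short anchor truss plus a weak
isotropic regularization spring (10⁻⁶ of the anchor's axial stiffness) —
trusses have no lateral stiffness, and for near-collinear chain segments
the joint would otherwise carry a zero-energy mode. The same "weak
springs" device is standard in commercial solvers; its effect on force
transfer is negligible and the unit tests assert the transverse compliance
remains orders of magnitude above the axial path.

Constraints per bite (six scalar DOFs, the minimum removing rigid-body
motion without blocking lateral deformation): bite-tooth tip dorsoventral;
molar — working TMJ {dorsoventral, anteroposterior}, balancing TMJ all
three; incisor — working TMJ all three, balancing TMJ {dorsoventral,
anteroposterior}. Muscle forces enter as nodal loads at strand origins
along the instantaneous first path segment.

The equivalent strain uses the effective-Poisson's-ratio convention
`ε_vM = √(½ Σ (εᵢ−εⱼ)²)/(1+ν_eff)` with ν_eff equal to the element's
material ν by default (a fixed value is configurable). It recovers the
axial strain under uniaxial stress and vanishes for hydrostatic states.
Stored strains are never clipped; any display saturation is left to the
viewer.

## Aggregation and statistics

The peak table keeps, per bone element, the maximum ε_vM over regimes
(tie → lowest regime index), the regime that produced it, and the extreme
tensile ε1 / compressive ε3 independently maximized over regimes. Teeth
and sutures (and pulp, PDL, links) are excluded from all statistics but
present in every solve. Bite-mode dominance classifies each element by
the mode of its argmax regime; principal dominance is compressive iff
|peak ε3| > peak ε1 (tie → tensile). Fractions are reported both
element-volume-weighted and element-count-weighted (identical on the
uniform-voxel phantom, distinct on general meshes). Histograms count
elements on half-open 20 µε bins; the remodelling band statistic is the
volume fraction with 100 µε < peak ε_vM < 1500 µε, bounds exclusive.

The sensitivity comparison re-solves all regimes with PDL/suture Young's
moduli scaled (×0.1 by default) and splits bone elements at a centroid
distance `d` (default 4 mm) from the nearest soft-tissue element. The
expected signature — and what the pipeline test asserts on the phantom —
is `median |Δpeak| (near) > median |Δpeak| (far)`, with the far median
non-increasing in `d`.

## Problem sizes and determinism

The packaged configurations use a 1 mm voxel phantom: ≈53 000 linear tets
(12 regimes) for `examples/full.yaml`, ≈35 000 (6 regimes) for
`examples/small.yaml`; the test suite runs the small configuration. These
sizes resolve every material layer at two-plus elements through-thickness
while keeping a full pipeline run (solves plus sensitivity variant) in the
minutes range on one CPU; the phantom refines via `cell_size` when finer
fields are wanted. Everything is deterministic — fixed geometry, direct
solvers, convex optimization with deterministic tie-breaking — so reruns
are bit-identical; the config `seed` is recorded for provenance and used
only by explicitly randomized test fixtures.

## Known limitations

* The phantom is a box-shell caricature; dominance percentages and band
  fractions computed on it characterize the *procedures*, not any animal.
* Muscle wrapping is polyline-based (no smooth-surface sliding), and
  Hill-type force–length–velocity dynamics are out of scope.
* The TMJ is a point constraint, not a contact analysis; strain
  concentrations at constraint nodes are artefacts to be read accordingly.
* Mid-cycle TMJ reaction recovery is least-squares (exact only where the
  QP closes the inter-TMJ moment, in particular at the snapshot).
* Bone is homogeneous and isotropic; no density-mapped stiffness,
  orthotropy, geometric nonlinearity, or adaptive remodelling.
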