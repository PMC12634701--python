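# Methods

This note documents the model behind `spinerod`: what is simulated, the
choices made where the design was genuinely open, and what the package's
tests do and do not establish about real spines.

## Scope and plane

The model is built and solved entirely in the sagittal plane: every body
(vertebrae T1..T12, L1..L5, S1; the pelvis is an immobile ground) carries
3 DOF (x anterior, z cranial, θ counter-clockwise viewed from the
patient's left, so positive θ is extension). All headline comparisons
between rod designs — junctional moments, screw loads, range of motion,
rod stresses — are sagittal quantities, which is what motivates the
restriction. The coronal lumbar Cobb angle is carried through as a scalar
descriptor only. Bilateral implants are collapsed onto the plane: the two
rods are one beam whose fiber areas are doubled (two identical parallel
rods at the same contour share one curvature field, so the reported fiber
stress *is* the per-rod stress), and each level's screw pair is one tie
whose force is reported per screw as half the sagittal resultant.
Consequently left/right force asymmetries cannot be represented; only
level means are meaningful.

## Geometry synthesis

`build_spine` realizes a requested radiographic profile exactly. The
pelvis is placed from PT (femoral-head axis to S1-endplate line tilted PT
from vertical, length 90 mm), the S1 endplate inclination is SS = PI − PT,
and TK / LL are apportioned over junction wedges using normative
fractions (lumbar lordosis weighted caudally — 12/16/20/26/26 % over
L1-L2..L5-S1 — thoracic kyphosis mildly apex-weighted). Upper-thoracic
junctions above the T4–T12 span receive 4 % of TK each so the cervico-
thoracic region follows the curve; the thoracolumbar junction T12-L1 is
neutral. Vertebral body and disc heights come from a versioned
average-adult table (`data/anthropometry.csv`), uniformly scalable.
Bodies have parallel endplates, so `measure_profile` recovers the request
to machine precision; the round-trip tolerance of 0.5° in the tests
covers future non-parallel extensions. Requested wedges beyond 25° per
junction are rejected as unreachable, naming the offending level range.

Segment masses: head + neck + both upper limbs (17.9 % of body mass)
lumped at T1, trunk slices of 2.1 % (thoracic) and 2.8 % (lumbar) per
level — about 55 % of body mass is supported at the lumbosacral junction.
Body mass defaults to 60 kg.

## Joint laws and their calibration status

Flexion/extension: M(θ) = κ·f·(k₀θ + c·sinh(θ/θ_ref)), odd and smoothly
stiffening; shear and axial are linear springs. κ ≥ 1 is the rib-cage
multiplier (1.6–2.0 thoracic, 1.3 at T12-L1, 1.0 lumbar); f ≤ 1
accumulates surgical release factors. The shipped per-junction table
(`data/joint_table.csv`) is an in-house plausible average-adult
parameterization chosen so that each lumbar FSU rotates 4–11° and each
thoracic FSU 2–8° under a pure 7.5 N·m flexion moment, consistent with
the spread of published cadaveric corridors. It is **not** calibrated to
any specific specimen set, so absolute simulated magnitudes (moments in
N·m, forces in N) are not comparable to any particular published model;
every simulation-level acceptance check is therefore a rank, ratio, or
direction property. Rotations beyond ±15° from rest clamp the law with a
logged warning as an extrapolation signal.

Surgical modifiers: facetectomy multiplies f (default 0.5 — the act is
standard, its magnitude is not, so it is configurable); a PSO wedge
shifts the joint rest angle; fusion makes the joint rigid. Inside the
solver, "rigid" is capped at 10⁴ N·m/deg — four orders above the
physiological laws (residual motion < 10⁻³ degrees at protocol load
levels) but low enough that equilibrium residuals stay above the
double-precision force floor. The joint-law API keeps the nominal rigid
limit of 10⁸ N·m/deg.

## Rod mechanics

Sections are discretized into 32 horizontal strips with exact
circle-segment areas and centroids, giving fiber-summed A exactly and EI
within 0.15 %. Each fiber follows a multilinear uniaxial elastoplastic
law (isotropic hardening to σ_u at 10 % elongation, flat beyond, with a
rupture flag) via a standard return map, so the section reproduces the
closed forms M_y = σ_y·I/c and, for the perfectly-plastic limit,
M_p = σ_y·d³/6 within 1 %, with path-dependent unloading.

Bezier diameter transitions are realized as a C1 cubic (smoothstep) blend
of d(s) over a 20 mm span centred on the named disc junction — the
transition length is a design choice (configurable); diameters are
plateaus within zones. A stepped profile changes diameter
discontinuously at its junction.

The rod mesh is co-rotational 2-node beams (8 per instrumented level,
two Gauss points, diameter sampled per Gauss point so smooth transitions
are resolved sub-element). The stress-free shape is the planned contour:
a cubic spline through the planned screw-head positions from an iliac
anchor 60 mm below the S1 head up to T10, with head targets 40 mm
posterior to each planned vertebral centroid. Element tangents are
assembled by per-element forward differences of the exact internal-force
function; with ~250 DOF a dense Newton solve is microseconds, and the
finite-difference tangent is robust through yield onset.

## Loads and the follower decision

Gravity is applied as a follower load: the compressive force transmitted
at each junction has magnitude equal to the cumulative supported weight
and acts along the current inter-centroid tangent; the net load on a
vertebra is the difference of its two junction forces. On a straight
vertical spine this telescopes to plain vertical gravity, and the force
reaching the sacrum always equals the total supported weight. The load
is evaluated from the *current* configuration inside the residual, with
its Jacobian added to the tangent by finite differences. A staged
variant (directions frozen at each load step) was tried first and
abandoned: with cadaveric-soft joints the upright spine is
buckling-unstable under fixed-direction compression — the follower load's
entire physiological meaning is that trunk musculature continuously
re-aligns the load path — and Newton cannot converge to an unstable
equilibrium. The flexion stage keeps the follower behaviour, which makes
the flexion test a clean rotation-driven load-transfer measurement: the
moment profile above the construct is then nearly uniform, as a
pure-couple test should show.

Standing calibration: the radiograph shows the *loaded* spine, so joint
rest angles and translational rest offsets are back-computed (Newton on
51 rest parameters against the 51 free equilibrium equations — the serial
chain is statically determinate) so that the built geometry is an exact
standing equilibrium. Rest shifts for the default case are < 0.3°.

## Staged protocol

1. **preop_standing** — built geometry under follower gravity (exact by
   calibration).
2. **prone** — gravity ramped to zero; supported prone positioning is
   modelled as unloading. This moves TK down and LL up (direction as
   expected); the magnitude of the prone change is small here because a
   follower-loaded spine stores little bending, another consequence of
   the uncalibrated joint table.
3. **released** — facetectomy factors applied at T10-T11..L5-S1 except
   the two junctions adjacent to L3, which belong to the PSO.
4. **instrumented** — the PSO wedge is auto-selected: the planned
   post-op junction angles keep released wedges everywhere except the two
   PSO junctions, which absorb the lordosis deficit to the plan target
   (LL 48°) up to a 35° cap, overflow spread over the facetectomized
   lumbar junctions. The wedge closure is displacement-controlled
   (rest-angle ramp), concurrent with reduction: ties between screw heads
   and rod nodes carry a rest mismatch ramped from the initial
   head-to-rod gap to zero — polyaxial heads rotate freely during
   reduction and are locked at their achieved relative angle at the end,
   after which both PSO junctions fuse. A residual head-to-rod gap above
   2 mm is an error ("tie target unreachable"). Modelling the PSO as a
   split wedge across L2-L3 and L3-L4, both fused, mirrors how loads
   cannot be attributed across the osteotomized level.
5. **postop_standing** — follower gravity ramped back on.
6. **flexed** — the T1 sagittal rotation is fixed 10° forward of its
   standing value (translations free) and ramped in.

Each stage starts from the previous converged state; rod plastic state is
committed after every converged load step (10 by default, Newton to a
relative residual of 10⁻⁶ with backtracking line search).

## What the synthetic conditions do and do not show

The generator's defaults *are* the study conditions: one severe
thoracolumbar-kyphosis case (PI 60°, PT 49°, TK 50°, LL −12°, 60 kg),
instrumentation T10–pelvis, PSO at L3, plan LL 48°, 10° flexion. Under
them the package reproduces, as properties: exact UIV+1 moment ranking
with length-averaged EI across the five rods; equivalent correction
(post-op LL spread < 0.1°, PI−LL ≈ 12°); construct stabilization
(instrumented ROM 30–40× below UIV+1 ROM); near-uniform above-UIV
moments; and a local stress excess of the stepped rod over the Bezier rod
at the transition, clearest at the locked state (the step concentrates
curvature demand in the smaller section; classical notch concentration is
outside beam resolution).

Not shown at desk scale: absolute junctional moments and screw forces (a
patient-calibrated joint set would be needed — simulated UIV+1 moments
are ~1.6 N·m against hundreds-of-N screw loads in full-scale FEM); rod
yield during correction (soft released joints let the spine, not the
rod, do the conforming); and the per-screw force *ranking* across rods,
which at these load levels is dominated by reduction/gravity locked-in
forces (~15 N) rather than the flexion-driven transfer (~5 N) — the
shipped reference tables carry that ranking instead. Left/right screw
asymmetry is unrepresentable by construction.

## Numerical choices

Tie stiffness 10⁵ N/mm and 10⁸ N·mm/rad (locked); solver-level fused
stiffness 10⁴ N·m/deg; fiber count 32 (48 where a 1 % plastic-moment
check needs it); 8 beam elements per instrumented level; 10 load steps
per stage; Newton tolerance 10⁻⁶ relative to the larger of applied-load
and step-start internal-force norms (floor 1 N); maximum 50 iterations
with up to 6 line-search halvings. Well-posedness is screened at
assembly by a diagonally-scaled eigenvalue test that names the dominant
rigid-body mode. Degenerate inputs fail loudly: non-positive diameters,
inconsistent pelvic parameters, unreachable apportionments or tie
targets, conflicting rotation constraints.

Problem sizes were chosen for a laptop-class run: the full five-scenario
protocol is ~250 DOF and ~30 s; the acceptance script and the whole test
suite each finish in about a minute.

## Known limitations

Sagittal plane only; no muscles (the follower load is their surrogate);
no pelvic version change pre/post; rod contouring residual stresses and
set-screw mechanics not modelled; prone positioning as pure unloading;
joint table uncalibrated to specimens (all corridor-dependent outputs are
rank/ratio-validated only); beam theory cannot express 3D notch stress
concentration at a step, only the section-mismatch concentration.
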