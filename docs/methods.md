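# Methods

This note documents the models and numerical choices behind `mrsim`, the
parameters that matter, what the synthetic generators do and do not emulate,
and the known limitations.

## Conventions

Quaternions are scalar-first `[w, x, y, z]`, unit norm, canonical sign
`w ≥ 0`. Exponential-map rotation vectors are in radians (direction = axis,
magnitude = angle) and are canonicalized to magnitude ≤ π. All frames are
right-handed. Capture-domain lengths are millimetres; the scene uses
centimetres (scale factor 0.1); FEM meshes carry whatever length unit their
coordinates are in, with stresses in pascals when moduli are in pascals and
forces in newtons with consistent lengths.

## Rotation conversions

`expmap_to_quaternion` is the closed form
`q = (cos(θ/2), sin(θ/2)·r/θ)` with `θ = ‖r‖`. Below θ = 1e-8 rad the factor
`sin(θ/2)/θ` is replaced by its 2nd-order Taylor expansion `1/2 − θ²/48`,
which avoids dividing by a vanishing norm without a discontinuity. The
inverse uses `θ = 2·atan2(‖v‖, w)` rather than `2·acos(w)`: the arccos form
loses half the significant digits near identity, the atan2 form does not.
For the same reason the geodesic distance between quaternions is computed
from the chordal distance (`4·asin(d/2)`), accurate at the 1e-9 tolerances
the test suite asserts.

## Rigid registration

`fit_rigid_transform` is the SVD least-squares (Kabsch) solution of the
absolute orientation problem: centre both clouds, SVD the cross-covariance
`H = Σ x̃ᵢ ỹᵢᵀ`, and take `R = V·diag(1,1,det(VUᵀ))·Uᵀ` — the determinant
factor flips the smallest singular direction whenever the unconstrained
optimum is a reflection, so `det R = +1` always. The translation is
`t = ȳ − R x̄`. The test suite cross-checks this route against an
independent implementation of the quaternion-eigenvector closed form
(Horn's method) to 1e-9.

Degeneracy: a unique rotation requires the source and target clouds to span
at least a plane. The collinearity test is `s₂ < 1e-9·s₁` on the singular
values of the centred cloud — i.e. numerical rank ≤ 1. (A test on the
*smallest* singular value would wrongly reject planar sets, and three
markers — the minimum trackable configuration — are always planar.)
Under-determined configurations raise rather than return an arbitrary
rotation, because a silently arbitrary registration is exactly the failure
mode the residual report exists to prevent.

Weighting is uniform: nothing in the capture stream provides per-marker
confidence, so no weights are invented. Scale is never estimated — unit
conversion is an explicit, separate step in the motion pipeline.

Surface picks snap to the nearest point on the mesh (exhaustive
point-triangle projection; meshes here are small). The snap tolerance
defaults to 1% of the bounding-box diagonal; picks farther away are rejected
as mis-picks. A configurable minimum-separation warning flags marker pairs
placed too close together, which degrades tracking accuracy.

## Tracking-model files

The XML dialect is documented in `docs/vsk-dialect.md`. The root segment is
a free joint with exactly six degrees of freedom; marker coordinates are
root-relative, making the file independent of the mesh's world placement.
The marker radius element defaults to 0.5. Numbers are written `%.6f` with
LF endings so write→read→write is byte-identical; reads are lenient (foreign
elements preserved verbatim, missing radius defaulted with a logged warning)
to interoperate with files from real tracker software without round-trip
loss. Articulated multi-segment chains are out of scope: only a fixed
inter-segment composition is meaningful to consuming code.

## Motion pipeline

**Conversion.** Translations are multiplied by the scene scale (default 0.1,
mm→cm); rotations go through `expmap_to_quaternion`. The 200 Hz capture /
~30 Hz render loop of a live rig is replayed offline from files; rate fields
are metadata.

**Low-pass filter.** A single-pole exponential smoother
`y_k = (1−α)·y_{k−1} + α·x_k` — the simplest causal low-pass, chosen because
the vibration problem it addresses needs nothing more and its group delay
(≈ (1−α)/α samples) is easy to state. DC gain is exactly 1; the magnitude
response is `|H(ω)| = α/√(1 − 2(1−α)cos ω + (1−α)²)`, giving `α/(2−α)` at
Nyquist; both are asserted against a simulated steady state. Rotations are
smoothed by spherical interpolation toward the previous *filtered*
orientation with the same factor — componentwise filtering of exponential
maps is not rotation-consistent (it cuts chords through the rotation group),
while incremental slerp stays on the unit-quaternion manifold. The
latency-vs-smoothing trade-off is exposed through α; no value is tuned to
any particular rig.

**Occlusion gaps.** Runs of frames with no pose for an object are filled by
timestamp-parameterized linear interpolation of translation and slerp of
rotation when the gap is ≤ `max_gap` frames and flanked by observations.
Longer gaps and gaps touching a stream boundary are reported, never
extrapolated. Originally observed frames are never modified, which makes
the operation idempotent.

**Flip detection.** Marker occlusion can make a tracker re-solve an object
upside-down. Frames whose geodesic rotation distance to the previous
observed frame exceeds a threshold (default π/2) are flagged; a persistent
flip is flagged once at onset, a single-frame flip at onset and recovery.

**Force monitor.** One `WarningEvent` per contiguous excursion of the force
trace strictly above the threshold (default 20 N, the critical instrument
force above which vertebral endplate / spinal-cord injury is risked),
stamped at the first exceeding sample. Strict inequality: a sample exactly
at the threshold does not warn. One event per excursion, not per sample,
avoids flooding the trainee with repeated warnings.

## Static FEM

Linear isotropic elasticity on 4-node constant-strain tetrahedra. Element
matrices are `Kₑ = V·BᵀDB` with the standard constant `B` from the linear
shape-function gradients; assembly is sparse; Dirichlet conditions (zero via
`constrained_nodes`, non-zero via `prescribed`) are imposed by row/column
elimination — exact and well-conditioned, unlike penalty methods. A singular
reduced system raises an error naming the null-space dimension (computed by
an eigenvalue scan) instead of returning garbage. Element orientation is
fixed at construction (node swap for negative volumes); zero-volume elements
are rejected.

Per-element stress is `σ = D B uₑ` (constant per element), reduced to the
von Mises equivalent
`σᵥ = √(½[(σ₁₁−σ₂₂)² + (σ₂₂−σ₃₃)² + (σ₃₃−σ₁₁)²] + 3(σ₁₂²+σ₂₃²+σ₁₃²))`.

**Critical force.** The failure criterion is *max von Mises ≥ yield stress*,
with the yield stress an explicit user parameter — no default pretends to be
a biological truth. Because the problem is linear, stresses scale with the
load magnitude and one unit-load solve gives
`F_crit = yield / max σᵥ(unit load)`. A bisection fallback (re-solving at
each magnitude) exists for future nonlinear extensions and must agree with
the linear formula within the tolerance on linear problems; the test suite
asserts this. The critical region is the element set above the
`(1−fraction)` von Mises quantile, with a 1e-9 relative slack so a
numerically uniform field counts as a single tie.

**Verification.** The solver is checked by: a patch test (prescribed uniform
strain on the boundary reproduces the analytic uniform stress to 1e-8
relative); a uniaxial bar whose tip displacement matches `F·L/(E·A)` within
2% on a 6×2×2-element block — and to machine precision with ν = 0 and
consistent tip tractions, where the exact solution lies in the element
space; global equilibrium of reactions vs loads to 1e-8 relative; exactly 6
near-zero eigenvalues of the free-free stiffness; and monotone convergence
of the bar error over 3 refinement levels.

**Material defaults.** The shipped `E = 12 GPa, ν = 0.3` are bone-like
placeholder values of cortical-bone order, clearly labelled
non-authoritative; any quantitative use must supply measured properties.

**Limitations.** Tet4 elements lock in bending and under-resolve stress
concentrations on coarse meshes; contact, large deformation and dynamic
impact are out of scope. Patient-specific geometry and boundary conditions
are not reproducible from published information, so critical-force numbers
computed here apply to the meshes given to the solver, not to any real
vertebra.

## Synthetic generators

All generators are pure functions of their parameters and a seed (single
PCG64 generator per call), so fixtures are bit-reproducible across
platforms.

- `gen_marker_cloud` rejection-samples points in a 100 mm box (defaults:
  ≥ 20 mm pairwise separation) until the set is non-collinear and has **no
  nontrivial point symmetry** — asymmetric placement is what lets a tracker
  distinguish left from right and avoid upside-down solutions. The symmetry
  check enumerates distance-matrix-preserving permutations by backtracking
  and verifies each candidate with an orthogonal Procrustes fit
  (reflections included).
- `gen_rigid_trajectory` moves the marker set along a smooth quasi-periodic
  rigid path (incommensurate sinusoids, defaults: 100 mm translation
  amplitude, 1 rad/s angular velocity, 200 Hz, matching a desk-scale capture
  volume and a hand-guided instrument), adds iid isotropic Gaussian noise to
  the marker positions — the simplest model that exercises the filter and
  the registration error paths — and re-solves the delivered per-frame pose
  from the noisy markers by least squares, exactly as an optical tracker
  does. Frames drop with Bernoulli probability; ground-truth poses are
  returned for recovery tests.
- `gen_block_tetmesh` subdivides each cell of a structured hexahedral grid
  into the 6 Kuhn tetrahedra (conforming across cells), giving closed-form
  node/element counts and exact volume.
- `gen_ellipsoid_mesh` scales a subdivided icosphere by the semi-axes, so
  every vertex lies on the ellipsoid to rounding.

Not emulated: camera projection and visibility geometry, marker merging,
calibration residuals, reflective clutter, correlated (non-white) noise.
Passing recovery tests therefore bounds *algorithmic* error under the stated
noise model; they do not certify accuracy on a physical rig.

## Problem sizes

The verification problems are deliberately desk-scale: 1000-transform
registration sweeps, 600-frame streams, FEM blocks of 48–144 elements and
50-replicate noise studies — sizes at which every analytic comparison in the
suite is exact or statistically stable, chosen as the package's own test
conditions.

## Pipeline and CLI

`run_pipeline` chains occlusion filling → low-pass → flip detection → scene
conversion (composing the registration transform when a tracking model and
correspondence are configured) → force monitoring, and writes a scene-pose
CSV, a warning log and a JSON run report echoing the full configuration.
Identical config and seed give byte-identical outputs. CLI exit codes: 0
success, 2 configuration/argument, 3 I/O or file format, 4 numerical
(under-determined registration, singular stiffness, infeasible sampling).
Tet meshes are read/written as legacy ASCII VTK unstructured grids and Gmsh
MSH 2.2; surface meshes via OBJ/STL/PLY (trimesh).
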