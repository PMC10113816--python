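# Methods

## Scope and design

`padtorsion` computes, from tracked skin-feature trajectories, per-frame
contact masks and 1 kHz force/torque traces, the surface-mechanics
description of a finger pad under pure torsion: Green–Lagrange strain
fields on a Delaunay mesh of the tracked features, slip classification and
the stick ratio, the full-slip event, contact-area size/orientation and the
peeling-vs-deformation decomposition of its change, strain energy, and the
torque-derived friction quantities. Feature detection/tracking of raw video
is out of scope (mature tooling exists); the package starts at the
trajectory table. Because no public raw-video dataset exists for this kind
of experiment, a synthetic trial generator with analytic ground truth is a
first-class component: every recovery claim in the test suite is a claim
about the generator's known answers.

## The synthetic torsion trial

One trial emulates: plate contact at normal force `F_N`, a 1 s pause, a
rotation of 80° at angular velocity `ω` about the contact normal, and a 1 s
hold. Imaging is one frame per degree of plate rotation (so the frame rate
in Hz equals `ω` in °/s and per-frame thresholds transfer across speeds),
at 85 px/mm. Components:

- **Contact geometry.** An ellipse of area `A₀ = a·F_N^b` (defaults
  a = 113.59 mm², b = 0.21, the reported means of the reference
  experiment), aspect ratio 0.8, tilted 15° from the image y-axis. The
  rotation centre is the ellipse centroid (exposed as a parameter; the real
  apparatus fixes it mechanically).
- **Features.** A hexagonal lattice with pitch 0.2254 mm (mean Delaunay
  triangle 0.022 mm², the reference scale), jittered by 15% of the pitch,
  clipped to the ellipse.
- **Slip-front kinematics.** The stick radius shrinks linearly with twist,
  `ρ_s(θ) = max(0, 1 − g·θ)` in normalized elliptical radius, g = 0.025/°
  by default. A feature co-rotates rigidly with the plate until the front
  reaches it, then decelerates along a smoothstep over one band width
  (0.3 mm, ≈1.9° of plate rotation at the default geometry) and is frozen
  at its slip-time position thereafter. The linear schedule is a stand-in:
  the phenomenon (periphery-first propagation) is documented, a
  quantitative law is not; recovery tests therefore compare against the
  generator's own schedule, never against human-trial values. Triangles
  straddling the moving front mix co-rotating and frozen vertices, which
  reproduces the counter-rotation zone seen at real slip fronts (rotation
  rate about the centroid opposing the plate).
- **Ground-truth full slip** is defined operationally, matching the
  detector: the twist at which the stuck-area fraction (front midline at
  `ρ_c = 1 − g·(θ − δ/2)`, stuck fraction `ρ_c²`) crosses the 0.03 stick
  cutoff; in closed form `θ_fs = (1 − √0.03)/g + δ/2` (≈34° at defaults,
  inside the 16–59° range human trials span). If a trial's rotation never
  reaches it, the event is absent (NaN).
- **Traction and torque.** Pressure is uniform by default (a loaded finger
  pad is flat and conforming; a Hertzian profile `p ∝ √(1−ρ²)` is
  available). The local friction coefficient weakens with pressure,
  `μ(p) = μ₀ (p/p_ref)^(−α)` with μ₀ = 1.57 at p_ref = 10 kPa and α = 0.44
  — the standard account of why finger friction falls with load. The torque
  is the traction integral over the sliding annulus,
  `T(θ) = ∫_{ρ>ρ_c(θ)} μ(p) p r dA`, evaluated by quadrature (polar-angle
  arc factor × cumulative radial integral); it rises monotonically from 0
  to the plateau `C(1)`. These defaults make the emergent friction law land
  at k ≈ 6.7 mm, n ≈ 0.76 and μ_rot fall from ≈8 mm at 0.5 N to ≈4 mm at
  10 N, the scales the reference experiment reports; they were fixed from
  that calibration, not adjusted afterwards. The generator also exposes the
  analytic exponent of its own law (`analytic_friction_exponent`), which
  equals `b(1/2+α) − α` for the uniform profile: the contact-area exponent
  and the friction exponent are related but *not* equal (n−1 = −0.24 vs
  b = 0.21 at defaults), consistent with contact mechanics.
- **Peeling and masks.** Peeling removes an outer *material* annulus at
  `peel_rate` (default 0.2 mm²/°, i.e. ≈12% area loss over a full trial, a
  peeling-dominated reduction of realistic size). The per-frame mask is the
  forward image of the non-peeled material disc under the twist map — a
  scaled copy of the initial ellipse rigidly rotated by the boundary
  material's accumulated twist (~3° per trial, so the contact re-orients
  slightly, as real contacts do). Because the twist map is a bijection,
  skin is inside the mask exactly when its material coordinate is inside
  the non-peeled disc; an earlier lab-fixed shrinking mask let sheared skin
  slide across a static boundary and biased the peel estimate with an
  artefact the physical system cannot produce.
- **Noise.** Isotropic Gaussian tracking noise per coordinate per frame
  (default 0.1 px, typical sub-pixel accuracy of pyramidal Lucas–Kanade
  tracking), added after the kinematics; force/torque sensor noise at the
  reference hardware's unloaded levels (0.0069 N, 0.087 mN·m). All
  randomness flows from a single mandatory seed through spawned generator
  streams; identical parameters give bit-identical outputs.

### What the generator does not emulate

Fingerprint-ridge texture and moisture/occlusion contrast changes;
viscoelastic bulk mechanics (the rate dependence of peeling seen in real
fingers); elastic rebound after the plate stops; inter-individual
variability (one parameter set = one idealized finger); slipped skin is
frozen rather than elastically relaxing, so late-trial cumulative shear
near the periphery grows linearly with radius rather than saturating.
Passing recovery tests therefore shows the *analysis* is correct about a
contact whose kinematic structure matches the model, not that the model
captures every property of human skin.

## Analysis choices

- **Smoothing.** Displacements are smoothed in *time* (the σ = 0.75 is in
  frames) with a normalized Gaussian. A nominal even window (N = 16) cannot
  be zero-phase on the sample grid, so the kernel is built on the symmetric
  odd support −8..8 and renormalized after truncation; constant and linear
  trajectories pass unchanged. With σ = 0.75 the taps beyond ±3 are
  negligible, so the distinction from any other reasonable truncation is
  immaterial.
- **Strain.** The deformation gradient is the affine map defined by the
  three vertices (exact for triangles), per consecutive frame pair;
  Green–Lagrange strains are exact for finite rigid motions (nullity is
  tested to 1e−10 over 1000 random motions). Principal strains come from
  the closed-form 2×2 eigendecomposition; the isotropic tie-break sets the
  orientation to 0°. "Total" strain maps sum per-interval invariants
  (default) — the natural companion of per-frame rate displays — with a
  last-vs-first-frame alternative (`endpoint_strain`); the two agree only
  for small increments. Note that summed `e_s` is non-negative per
  interval, so tracking noise accumulates as a positive bias in long
  trials; at the default 0.1 px noise this inflates `|e_s,end|` medians
  noticeably (the same bias affects any pipeline that sums shear
  magnitudes).
- **Slip.** Rotation rate = mean signed angle swept by the three
  centroid-to-vertex vectors; threshold 0.6°/frame with no persistence (the
  0.03 stick-ratio cutoff absorbs re-stick flicker); the stick ratio is
  area-weighted over in-contact triangles. The boundary between stuck and
  slipping skin is traced by nearest-neighbour interpolation of the flags
  onto a 4 px (~0.05 mm) grid restricted to the centroid hull, taking the
  largest connected stuck component's marching-squares contour
  (nearest-neighbour chosen because the flags are binary; linear
  interpolation is offered as an option). Detection noise: with the fixed
  smoothing above, 0.1 px tracking noise leaves ≈0.15°/frame of
  rotation-rate noise on 0.022 mm² triangles — comfortably under the
  threshold — but 0.3 px leaves ≈0.5°/frame, which floors the stick ratio
  near 0.2 and defeats the 0.03 cutoff; the method as published presupposes
  tracking errors ≲0.15 px.
- **Contact.** Area = pixel count / (85 px/mm)²; tilt from the mask's
  second central moments (equivalent to a contour ellipse fit for filled
  regions), defined as the angle from the image y-axis in (−90°, 90°],
  undefined (flagged NaN) for near-circular masks. A triangle is in contact
  iff all three vertex pixels (nearest-pixel sample) are inside the mask;
  inside→outside transitions add the triangle's current area to peeling,
  the reverse to laying; deformation sums area changes of triangles in
  contact at both frames; the residual closes the per-frame accounting
  identity exactly. The all-3-vertices rule has a known resolution limit:
  it counts the whole band of triangles *touching* the peeled annulus, an
  offset of about one triangle row along the contact edge (≈2.7 mm² at the
  default density) that appears as the residual. Peel estimates are
  therefore biased high by that fixed amount — measured to track the
  material band area to within 0.1% — and peel magnitudes below a few
  triangle rows cannot be resolved at the published mesh density.
- **Friction.** Zero-phase (forward-backward) Butterworth, order 2, 5 Hz;
  `T_slip` anchored at 75° to stay clear of the deceleration phase; |T| is
  used throughout so both rotation directions share one code path. Power
  laws are fitted by nonlinear least squares in linear space (initialized
  from the log-log line; log-log fitting is a switch, and both r² values
  are reported, since the fitting space is a genuine free choice). External
  work `W = ∫ T dθ` uses |T| against the unsigned twist so work done on the
  finger is positive; W ≥ U holds on every trial.
- **Energy.** `U = p·Σ u_d·Aᵢ` with areas in m²; the stored-energy time
  series evaluates `u_d` on the cumulative (summed) tensor per frame, and
  the rate `dU/dt` is the discrete derivative reported at interval
  midpoints so its rectangle integral reproduces U exactly.

## Test and acceptance problem sizes

Unit tests run coarse trials (0.45–0.6 mm feature spacing, ≈800 features)
where exactness, not resolution, is at stake; recovery and acceptance tests
run the default density (0.2254 mm, ≈3000 features, ≈5900 triangles, 83
frames) — the scale of the reference data — across the five-force,
two-direction grid. The acceptance script's ladder uses 5 forces × 5
repetitions with 2% trial-to-trial friction variability.

## Known limitations

- The peel estimator's one-triangle-row offset (above) means the
  "cumulative peeled vs configured schedule" check holds only to ≈15–20%
  at the published mesh density, not to 5%; the accounting identity itself
  is exact. Finer lattices shrink the offset linearly.
- Per-triangle strain against a smooth analytic field converges only at
  first order where the field's curvature is large (the affine fit's
  gradient error alternates in sign between the two lattice orientations),
  so pointwise oracle checks are made on the front annulus at spacings a
  few times finer than the band.
- Slip is undetectable near the rotation centre (displacements below
  resolution); the 0.03 cutoff is the operational answer, and stick ratios
  below it are not meaningful.
- Strain-energy magnitudes inherit the arbitrary 2 mm depth convention and
  should only be compared with numbers sharing it.
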