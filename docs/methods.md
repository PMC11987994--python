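# Methods

This note records the models, conventions and numerical choices behind
fishtrack3d, and what its synthetic validation does and does not establish.

## Coordinate conventions and calibration

The tank frame is right-handed with the origin at the front-left-bottom
corner: x along the long side (540 mm), y up from the bottom through the
water column (200 mm usable), z along the short side (370 mm).  Pixels are
0-based and continuous; pixel (u, v) covers [u, u+1) × [v, v+1).  The front
camera maps u→x and v→y with v flipped (top image row = water surface); the
top camera maps u→x and v→z.

Calibration is a per-axis linear scale from the crop rectangle to the tank
extents.  No lens distortion or water-refraction model is applied: with
consumer webcams 0.8–1 m from a small tank and no available intrinsics, a
refraction model would add unverifiable parameters.  The resulting bias is
absorbed into the measurement error and is the main caveat when interpreting
absolute millimetre positions near the tank walls.  Mapped coordinates that
overshoot the tank by a pixel (edge detections on the glass) are clamped and
logged rather than rejected.

The y (height) reference is the water column, not the glass wall height: the
fish cannot occupy the air gap, and using water height makes occupancy plots
directly comparable across fill levels.

## Detection pipeline

Stage order: crop → reference subtraction → grayscale → pre-clean → dense
flow → motion mask → Canny → dilation → largest component → convex hull.

* **Reference subtraction** is a per-pixel absolute difference against an
  empty-tank frame, then BT.601 luminance.  Static scene content — including
  the camera's faint reflection in the glass — cancels identically, which is
  why a constant artifact can never be detected (verified by the
  static-scene benchmark).
* **Pre-clean** (3×3 median filter, then zeroing values below
  `diff_floor` = 15 of 255): the subtracted background is sensor noise that
  is uncorrelated between frames; fed raw to any local flow matcher it
  produces large spurious flow everywhere.  Flooring makes the background
  exactly flat, where flow is identically zero.  The floor must stay well
  below the fish-to-background contrast (≥ 20 levels by construction in the
  renderer; ~80 in defaults).
* **Dense flow** uses scikit-image's coarse-to-fine iterative Lucas–Kanade
  solver (`radius=5`, `num_warp=3`), a local least-squares matcher inside a
  Gaussian pyramid; it follows the 5–30 px/frame displacements that a
  1 frame/s capture rate produces.  `flow_downscale` (default 1; 2 is used
  for ≥640 px frames by the validation harnesses) block-averages the inputs
  before the flow stage and rescales magnitudes, since the mask is only a
  gate and tolerates 2 px quantisation.
* **Motion gate.** The mask keeps pixels with flow magnitude ≥ `mag_thresh`
  (1 px/frame, inclusive).  Local flow estimators overestimate sub-pixel
  motion of a flat blob — rasterisation jitter looks like structure; we
  measured median flows of 2–6 px for a true 0.6 px shift with both the
  iterative-LK and TV-L1 solvers.  A phase-correlation estimate of the rigid
  shift between the two subtracted grayscales (accurate to ~0.3 px, ~4 ms)
  therefore verifies the displacement first; frames below `mag_thresh` are
  reported `missing`.  This keeps the semantics "no motion ⇒ no
  displacement" exact and makes the recovered distance a conservative
  (never inflated) estimate.
* **Shape extraction.** Canny (σ=1, thresholds 50/150 on the 0–255 scale)
  runs on the motion-gated grayscale; running it on the flow-magnitude image
  instead is supported (`canny_on="flow_mag"`) but gives softer edges.  The
  mask is first grown by `mask_dilate_px` so the whole silhouette survives
  the gate.  Edges are dilated with a disk footprint (diameter `kernel_px`,
  `dilate_iter` passes) to close the outline; the largest 8-connected
  component with ≥ `min_area_px` pixels wins (ties: uppermost, then leftmost
  bounding-box origin).  The convex hull of the component's pixel-corner
  points is "the minimal polygon covering the area"; position is the hull's
  area centroid, size its area, orientation the long side of its
  minimum-area enclosing rectangle (rotating calipers), in [0°, 180°).
  Note the hull area exceeds the fish's body area by the dilation margin;
  it is a relative size figure, not a calibrated body area.

Defaults are calibrated for ~640×360 working resolution; `min_area_px`
scales with pixel area and the others with linear pixel size.

## Fusion and metrics

Views are joined on exact capture timestamp (duplicate timestamps within a
view are an error; one-view-only timestamps are reported).  x is the mean of
the two views' estimates — the tank is shallow and both cameras are far, so
neither view is privileged — with |Δx| logged and values > 50 mm flagged.
If either view is missing, the previous fused point is carried forward
(`source="carried"`, zero speed); pairs before the first full detection are
dropped.

Speed(t₀)=0 by convention, so an N-sample track yields N speeds and
⌊N/10⌋ windows — the only reading under which a 10 h, 1 Hz experiment gives
exactly 3,600 non-overlapping 10 s windows.  Carried spans contribute zero:
distance is under- rather than over-estimated when the animal is still or
moving below the motion threshold.

Detection rate, when we quote it, is computed over frames whose true
in-view displacement is at least twice the flow threshold: motion along the
axis a view cannot see (e.g. pure depth motion for the front camera) is
legitimately invisible to that view and handled by carry-forward, not a
detector failure.

## Statistics

Kruskal–Wallis goes through scipy (tie-corrected H, χ²_{k−1} p-value; the
all-values-identical degenerate case returns H=0, p=1).  Dunn's test is
implemented in-package: mean mid-ranks on the pooled sample, variance
N(N+1)/12 − T/(12(N−1)) with the usual tie sum T = Σ(t³−t), two-sided normal
p-values × k(k−1)/2, capped at 1, unit diagonal.  Both kernels are checked
against from-scratch rank oracles to 1e-10 in the test suite.  Dunn runs
unconditionally; the omnibus result is stored as a gate flag because the
protocol applies the post hoc only after a significant omnibus.

The KS normality screen estimates μ and σ from the sample, which biases its
p-value upward (Lilliefors effect).  It is deliberately only a gate for
choosing the nonparametric route — never an inferential endpoint — so the
bias is documented rather than corrected.

The surrogate-group generator draws from normals truncated at zero (speeds
are non-negative) with pre-truncation moments set by a four-group template
(control / 100 / 200 / 400 mg·l⁻¹ analogues: means 91.24 / 83.87 / 52.11 /
24.22 mm/s, SDs 39.90 / 23.88 / 22.95 / 9.34).  Truncation shifts the
lowest-mean group's realised mean upward by ~0.1%; the closed-form
truncated-normal mean is the test oracle.

One caveat the surrogate model states explicitly: real windowed speeds are
serially dependent (the animal's behaviour has timescales longer than 10 s),
while surrogate draws are i.i.d.  Power and type-I results on surrogates
therefore bound the idealised behaviour of the tests, not their operating
characteristics on autocorrelated recordings; borderline pairwise outcomes
(p near α) should not be read off the surrogate harness.

## Synthetic scenes

The trajectory model is a correlated random walk: azimuth θ does a wrapped
random walk with per-step SD (1 − persistence)·π; pitch relaxes toward a
preference set by `bottom_bias` (+1 bottom, −1 surface); step length is
|N(μ, σ)|·dt; walls reflect specularly (position folded, heading mirrored).
Positions keep a 30 mm wall margin so the rendered body stays inside the
view.  Defaults (μ = 15 mm/s, σ = 4, persistence 0.8, 1 s steps) keep
per-frame displacements in the 5–30 px band at the default rendering scale —
the regime a pyramidal flow estimator can follow at 1 frame/s.  Ground-truth
distance is the sum of 3D distances between consecutive stored positions,
i.e. exactly what an ideal point tracker would integrate.

Rendering is orthographic (consistent with the linear calibration): the fish
is a filled ellipse (default semi-axes 30 × 11 px at 640×360, a
reduced-scale silhouette; what matters for the detector is the
displacement-to-body-size ratio, not absolute body size), oriented along the
projected heading, ≥ 20 intensity levels darker than the background.
Optional Gaussian pixel noise and a static artifact (drawn identically in
all frames and the reference) complete the scene.  Not emulated: perspective
and refraction, shadows and caustics, body articulation, occlusion at the
water surface, illumination drift.  Passing the synthetic benchmarks
therefore demonstrates the pipeline's geometric and statistical correctness
and its noise/artifact robustness, not photometric robustness on real
footage — thresholds (`diff_floor`, Canny) should be re-tuned on real
reference frames.

`dose_profile` scales the speed distribution's mean *and* SD by
(1 − suppression) — dosed groups show both slower and less variable
swimming — and `aggregation` pulls the depth preference toward the surface
and tightens turning, emulating late-phase surface confinement.

## Validation harness sizes

The shipped benchmarks use: 36,000 simulated steps for window arithmetic;
600 rendered frames per view at 640×360 (noise-free) for tracking recovery;
100 static frames at 320×180 for artifact rejection; 2,000 replicates of
n=100 four-group draws for type-I calibration; four rendered 180 s dose
scenes at 320×180 plus 200 statistical replicates at n=3,600 for the
dose–response pattern.  These sizes give stable estimates (binomial SE on
the type-I rate ≈ 0.5 pp) while keeping a full validation run within
minutes on a single CPU core.

## Known limitations

* Single animal only; no identity reasoning, no occlusion handling.
* Linear calibration ignores refraction: absolute positions near walls carry
  a systematic error that cancels in displacement-based metrics.
* The motion gate trades sensitivity for honesty: sustained swimming slower
  than ~1 px/frame is recorded as stillness.
* Hull area includes the dilation margin; orientation is modulo 180° (head
  and tail are not distinguished).
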