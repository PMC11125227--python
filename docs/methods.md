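# Methods

## Problem setting

Two keypoint detectors observe the same moving person: a depth camera
whose skeletal estimates jitter spatially during fast motion, and an
RGB-image detector whose estimates degrade as illumination falls.  A
marker-based motion-capture reference is available during calibration
only.  The goal is a single fused stream that inherits the RGB stream's
stability in good light and the depth stream's robustness in the dark,
without knowing the lighting in advance.

## Data model and alignment

Keypoints are the 12 limb joints (left/right shoulder, elbow, wrist,
hip, knee, ankle).  Each detector indexes joints differently; the
packaged catalog maps depth-scheme indices (4, 5, 6, 8, 9, 10, 12, 13,
14, 16, 17, 18) and rgb-scheme indices (11, 13, 15, 12, 14, 16, 23, 25,
27, 24, 26, 28) onto canonical names, and non-limb points are dropped.
Sequences store metres for 3-D data or pixels for projected 2-D data;
the unit travels in the CSV header so the two can never be mixed
silently.  Invalid joints carry NaN plus an explicit validity flag and
are excluded from every sum; a metric's denominator counts only samples
valid in both compared streams.  Occlusion handling in the reference
stream is our convention (no published one exists for this pairing).

Streams are synchronised by nearest-timestamp decimation to a common
rate (30 Hz by default), never by interpolation, and ties resolve to the
earlier frame.  The depth stream is brought into the reference frame by
a rigid transform p → R·p + T; pixel-space evaluation uses the pinhole
projection u = fx·X/Z + dx, v = fy·Y/Z + dy with the calibration scale s
applied before projection (default 1).  These are deliberately two
separate operations — a single matrix mixing intrinsics and extrinsics
is not a well-typed 3-D→3-D map — and calibration values are consumed
from config; estimating them is out of scope.

## Illumination model

Relighting happens in linear colour space.  The sRGB transfer uses the
constants 12.92, 1.055, 0.055, exponent 1/2.4 and linear breakpoint
0.0031; its inverse switches branches at the encoded value 12.92·0.0031,
which makes the round trip exact to better than 1e−9 everywhere except a
~5e−6-wide seam at the breakpoint that the branches of this constant set
leave unmatched.  The highlight-preserving inverse gain is

    f(x, g) = max(x·g, (1−α)·x·g + α·g),  α = (max(x−t, 0)/(1−t))²,

with gain x ∈ (0, 1] and threshold t (default 0.9, the conventional
highlight inflection of the unprocessing literature; both are config
options).  For x ≤ t the map is exactly linear (α = 0); for x > t the
blend pulls bright content toward its original value, so the output
never falls below plain gain x·g and never exceeds max(x·g, g).  α
depends on the gain only, as printed in the source model, not on the
pixel's grey level.  g is the linearised channel value in [0, 1]; no
separate CIE-XYZ conversion is modelled because the gamma transfer
consumes exactly this quantity.

Scene brightness x̄ — the predictor of the weight model — is the mean
linear Rec. 709 luminance (0.2126 R + 0.7152 G + 0.0722 B after
linearisation).  Any monotone scalar summary would serve; this one is a
single number per frame and is exactly proportional to the gain when
x ≤ t.

## Weight optimisation and the brightness model

The per-condition objective Mse(h) is a scalar quadratic, minimised with
the package's limited-memory BFGS engine: two-loop recursion over the
newest `num` (s, y) pairs (default 10), backtracking line search with
the Armijo sufficient-decrease condition (the descent scheme specifies
only a one-dimensional search; backtracking is the simplest compliant
choice), gradient threshold 1e−5, start h₀ = 0.5.  Non-positive-
curvature pairs are discarded.  Because the objective is quadratic in h,
the closed-form minimiser Σ⟨U′−V′, D−V′⟩ / Σ‖U′−V′‖² is computed
independently and serves as the oracle in tests; the iterative solver
must agree to 1e−6.  Weights are clamped to [0, 1] — h is a convex
blend, and the unconstrained optimum can leave the interval on
adversarial data (a warning-free clamp; the calibration table records
the achieved objective).  One global h per lighting condition is used,
not per joint or per axis.

The logistic fit h_est(x̄) = 1/(1 + e^(−a·x̄ + b)) minimises squared
error with the same engine in two dimensions.  Logistic least squares is
non-convex, so a fixed multi-start grid a ∈ {−20, −10, −5, 0, 5, 10,
20} × b ∈ {−10, −5, 0, 5, 10} is tried and the best final objective
kept.  During application the brightness may be supplied per frame or
per condition; the pipeline uses the per-condition value of its
calibration images.

## Kalman smoothing

Fused trajectories are filtered per joint with a constant-velocity
6-state model — the minimal dynamics consistent with initialising
velocity from a short history window.  Q = 0.08·I₆ and R = 0.2·I₃ apply
the published scalars to the full identity of each matrix's natural
dimension; units follow the data unit (px² or m²) and are overridable.
Initial position is the first valid frame, initial velocity the mean
finite difference over the first 30 frames (one second at 30 Hz), P₀ =
I₆.  Invalid measurements skip the correction step, so gaps are bridged
by prediction.  Covariances are re-symmetrised after every step.  The
filter is causal; a multi-step forecast (e.g. 30 frames ≈ one second
ahead) is exposed but not used downstream.

Note a deliberate property of the fixed Q/R pair: the steady-state gain
depends only on their ratio, giving a moderately smoothing filter
(position gain ≈ 0.46 at these values).  On slow or very noisy
trajectories it reduces error substantially; on the fast gait motif with
already-small fused noise the smoothed stream trades a little pixel
accuracy for smoothness, which the pipeline reports honestly as separate
`fused` and `smoothed` rows.

## Metrics

MSE, cosine similarity (flattened vectors), R² = 1 − SSres/SStot,
symmetric percentage difference, joint accuracy (fraction of samples
within a Euclidean pixel threshold; thresholds 6 and 8 by convention),
coefficient of variation (sample standard deviation over mean, percent),
SSIM and PSNR.  The percentage difference |F−D|/((F+D)/2) is undefined
for signed coordinates, so it is applied to non-negative quantities:
per-coordinate magnitudes by default, per-sample Euclidean norms as a
labelled variant.  SSIM is computed from global whole-image statistics
(single μ, σ², σ_pq per image, C₁ = (0.01 L)², C₂ = (0.03 L)²), exactly
as the closed formula reads; the sliding-window library convention is
available behind a flag but is not the default.  PSNR uses the
dynamic-range maximum (255 for 8-bit, 1.0 for float) with the observed
maximum available via an argument, and returns +inf for identical
images.  Joint accuracy is evaluated in 2-D pixel space after
projection.

## Synthetic study conditions

The generator emulates the structure of a rehabilitation recording
session, not its photometric realism:

- **Ground truth** — an articulated skeleton (rigid pelvis/torso,
  fixed-length limb segments of 0.28/0.25/0.40/0.40 m) whose joint
  angles are band-limited sinusoids (fundamental plus weak first
  harmonic).  Bone lengths are constant by construction.  The
  `gait_balance` motif swings hips/knees with large amplitude at 0.9 Hz
  (high leg lifts); `gravity_shift` is small-amplitude 0.4 Hz lateral
  sway.  Subject at 2.5 m from a 500 px focal-length camera, so 1 px ≈
  5 mm; noise magnitudes specified in pixels convert at that scale.
- **Depth stream** — truth plus isotropic Gaussian jitter (σ = 2 px)
  plus spikes on knees/ankles only: with probability 0.15 per sample the
  joint is displaced by ≥ 15 px in a random direction.  The spike
  probability is our choice, set so the depth stream's accuracy at
  threshold 8 sits at the top of the realistic 60–95 % band; the other
  magnitudes (2, 15, 1 px and darkness gain 8) are the fixture's stated
  defaults.  Depth noise is independent of illumination.
- **RGB stream** — truth plus Gaussian noise with
  σ = σ_base·(1 + k·(1 − b(x))), where b(x) is the brightness of the
  reference image relit at gain x *relative to full illumination*
  (b(1) = 1, and b(x) = x exactly while x ≤ t).  At gain 1 the RGB
  stream is less noisy than the depth stream; below roughly gain 0.6
  it is noisier — the crossover the adaptive weight must learn.
- **Images** — deterministic gradient/checker/gray patterns relit per
  gain; brightness x̄ is measured from these images, so the calibration
  consumes the same quantity a real pipeline would.

What passing tests on this generator do **not** show: detector-specific
bias (both streams are unbiased here), correlated or skeleton-structured
noise, occlusion patterns, rolling-shutter or motion-blur effects, and
any photometric coupling between the rendered images and the keypoint
noise beyond the shared gain variable.  Conclusions about real hardware
require real recordings.

## Problem sizes and numerical choices

Default scene: 300 frames (10 s at 30 Hz) × 12 joints × 5 gains
(1.0, 0.8, 0.6, 0.45, 0.3) — 18 000 jointly valid samples per sweep,
enough for stable calibration while keeping a full pipeline run in
seconds.  The optimiser-oracle sweep uses 50 datasets of 1200 samples;
the filter-benefit check uses 100 seeded 150-frame replicates at 5 px
measurement noise.  Ties in resampling go to the earlier frame;
degenerate fusion data (U′ ≡ V′) yields h = 0.5 with a warning;
zero-variance references make R² an error rather than a silent NaN; CV
uses the n−1 convention.  All generators and the pipeline are pure
functions of their seed.
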