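# kpfuse — light-adaptive fusion of multi-source human keypoint streams

`kpfuse` is a toolkit for movement-analysis and rehabilitation researchers
who track human limb joints with two complementary detectors at once: a
depth camera (accurate range, but spatially jittery while the person
moves) and an RGB pose detector (stable during motion, but unreliable in
poor light).  The package blends the two streams into a single keypoint
trajectory whose blend weight adapts to scene brightness, and smooths the
result with a per-joint Kalman filter.

## Method

For one lighting condition, with RGB-detector keypoints U′, aligned
depth-camera keypoints V′ and reference (marker-based motion capture)
keypoints D, the fused stream is the convex blend L = h·U′ + (1−h)·V′ and
the optimal weight minimises

    Mse(h) = (1/n) Σᵢ ‖ h·U′ᵢ + (1−h)·V′ᵢ − Dᵢ ‖²,

solved by a limited-memory BFGS iteration (two-loop recursion, Armijo
backtracking, gradient threshold ε = 1e−5, start h₀ = 0.5).  Lighting
conditions are produced by a highlight-preserving inverse-gain model in
linear colour space,

    f(x, g) = max(x·g, (1−α)·x·g + α·g),   α = (max(x−t, 0)/(1−t))²,

bracketed by the piecewise sRGB gamma transfer (constants 12.92, 1.055,
0.055, 1/2.4, breakpoint 0.0031).  The calibration pairs (x̄, h_best) —
scene brightness x̄ is mean linear Rec. 709 luminance — are fitted with a
logistic curve

    h_est(x̄) = 1 / (1 + e^(−a_est·x̄ + b_est)),

which predicts the blend weight for unseen lighting.  Fused trajectories
are filtered per joint with a constant-velocity Kalman filter
(Q = 0.08·I₆, R = 0.2·I₃).  Evaluation covers MSE, R², cosine
similarity, symmetric percentage difference, joint accuracy at pixel
thresholds 6 and 8, coefficient of variation, and global-statistics SSIM
and PSNR for the relit images.

Because no public recordings pair all three sources, the `synthetic`
module generates the study conditions: a smooth 12-joint skeleton with
exactly constant bone lengths, a jittery depth-like stream with
heavy-tailed spikes on knees/ankles, an RGB-like stream whose noise grows
as the scene darkens, and relit images per illumination gain.

## Worked example

```python
from kpfuse import LightAdaptiveFusion
from kpfuse.synthetic import SceneSpec, make_scene

bundle = make_scene(SceneSpec(n_frames=150, seed=0))
results = LightAdaptiveFusion(bundle.scenes()).fit()
print(results.summary())
```

prints

```
Light-adaptive fusion calibration
=================================================
conditions: 5    samples/condition: 1800
a_est (slope):   15.534872
b_est (offset):  3.232733
in-sample weight RMSE: 0.050083
-------------------------------------------------
   x_bar    h_best     h_fit  mse(h_best)
  0.0949    0.2007    0.1470  0.000662629
  0.1424    0.2784    0.2648  0.000603178
  0.1898    0.3836    0.4295  0.000514135
  0.2531    0.6305    0.6680  0.000315753
  0.3164    0.9204    0.8432  6.81339e-05
```

Each row is one lighting condition: `x_bar` is the measured scene
brightness, `h_best` the MSE-optimal blend weight for that condition
(weight on the RGB stream), `h_fit` the logistic model's prediction, and
`mse(h_best)` the fused error in m² at the optimum.  The positive slope
`a_est` is the adaptation itself: as the scene brightens, weight shifts
from the depth stream to the RGB stream.  `results.fuse(u, v, x_bar)`
then blends any aligned pair of streams at a given brightness.

The same flow is available from the shell:

```
kpfuse simulate --out scene/ --seed 0
kpfuse relight in.png out.png --gain 0.5
kpfuse run --seed 0 --report report.json
```

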