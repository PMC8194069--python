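# Methods

`flowpose` implements a multi-frame markerless pose-estimation pipeline:
single-frame keypoint confidence heatmaps are combined across a temporal
window using dense optical flow, evaluated with an acceptance-region
metric (aPCK), and optionally corrected across paired camera views.
This note records the model, the parameter choices, the numerical
decisions, and what the synthetic benchmark does and does not
demonstrate.

## Heatmap labels

A human annotation is a point `(x, y)` (continuous pixels, 0-based,
x = column, y = row, origin top-left) plus a per-keypoint acceptance box
`box_w x box_h` chosen by the labeller to cover the body part. The
label grid is a truncated 2D Gaussian: the PDF
`exp(-(c-x)^2 / 2*sigma_x^2 - (r-y)^2 / 2*sigma_y^2)` is evaluated at pixel
centres inside the box only (hard zero outside), rescaled so the maximum
is exactly 1.0, and every value strictly below 0.1 is zeroed. The box
is the `box_w x box_h` pixel window centred on the nearest in-image pixel
to the annotation, clipped to the image; with continuous coordinates the
discrete maximum therefore sits at the nearest pixel to the true peak.

* `sigma_frac` (default **0.25**, per axis): `sigma = box_dim * 0.25`
  places the box edge near 2 sigma. Larger values flatten the label and
  push more of the box above the 0.1 cut; smaller values shrink the
  nonzero support well inside the box. The value is a package
  convention — the acceptance region is ultimately whatever the 0.1 cut
  leaves nonzero.
* A pixel holding exactly 0.1 after thresholding is *inside* the
  support (only values strictly below 0.1 are zeroed).
* A keypoint absent from a frame yields an all-zero grid, is flagged,
  and is excluded from that keypoint's aPCK denominator.

For regression training the unit-peak labels are multiplied by a peak
value (default **16**) to increase label/background contrast, one copy
per supervision stage; evaluation-side labels are never scaled.

## aPCK evaluation

A prediction is *correct* when its decoded location (nearest pixel,
round-half-up) lands on a strictly positive pixel of the label grid;
the error rate is `1 - n_correct / n_evaluated`, pooled per keypoint
over frames, with absent-keypoint frames excluded from the denominator.
Summary statistics (mean, SD) weight keypoints equally. Predictions
decoded off-image count as incorrect. RMSE is provided for comparison
but aPCK is the primary metric: it adapts to keypoints of very
different physical sizes, which fixed-radius PCK variants and RMSE do
not. Model comparisons use a t-test paired by keypoint on per-keypoint
error rates.

## Temporal aggregation

For target frame `t`, skip ratio `s` (default **1**) and frame range
`f` (default **4**), the window holds the `2f+1` frames at indices
`t + k*s`, `k = -f..f`, clamped into the sequence (edge frames are
replicated rather than dropped, so output length equals input length).
The base predictor — any single-frame model producing one non-negative
heatmap per keypoint — is applied to every window frame. Dense optical
flow is computed from the *target* to each neighbour, and each
neighbour's heatmaps are morphed onto the target by backward bilinear
sampling (`morphed(p) = h(p + (u, v)(p))`); samples outside the grid
contribute zero confidence mass, because fabricating border mass would
bias decoding. The centre member is passed through unchanged. The
`2f+1` morphed stacks are combined pixelwise by a per-keypoint weight
vector — a 1x1 convolution over the window axis, i.e. a plain weighted
sum with no bias or nonlinearity. Decoding takes the per-keypoint
global maximum after clipping negative aggregate values to zero (raw
values are kept for fitting).

Weights are one vector per keypoint, shared across pixels. Sharing
across keypoints was rejected: keypoints differ in motion statistics
(e.g. paws vs. snout), and per-keypoint weights cost only `P*(2f+1)`
parameters. Mixing information *across* keypoints is a possible
extension, not implemented.

### Flow estimator

Dense flow uses the iterative Lucas–Kanade solver
(`skimage.registration.optical_flow_ilk`) on single-channel float32
frames (Rec.601 luminance for colour input). Parameters:

* `window_size` **27 px** (solver radius 13): the local integration
  window; must exceed the largest blob/limb displacement between window
  members.
* `num_warp` **2**: iterative warp refinements. On the known-shift
  oracle, displacements up to about half the window radius are
  recovered to sub-pixel accuracy with two warps; further refinements
  changed peak positions by less than 0.1 px on the benchmark scenes
  while costing proportionally more time.
* `gaussian` weighting on; no prefiltering.

Flow is computed on the raw (preprocessed) video frames, not on model
feature maps. Blank, gradient-free frames give finite but meaningless
flow — the simulator therefore always renders low-amplitude background
texture.

### Weight fitting

The aggregation weights minimise the MSE between the weighted sum of
morphed heatmaps and the (peak-scaled) label heatmaps. Two solvers are
provided and must agree: an exact per-keypoint linear least squares
(normal equations accumulated in float64 across windows; rank-deficient
systems — e.g. a static scene where all morphs coincide — fall back to
the minimum-norm solution with a warning), and minibatch Adam
(lr 1e-4, betas 0.9/0.999, **30 epochs**, uniform `1/(2f+1)` init,
batch 64). Adam's travel per weight is bounded by the learning rate
times the step count, so the small batch size is what makes the fixed
budget of 30 epochs at lr 1e-4 sufficient; the least-squares path is
the default everywhere.

Sequence-level runs cache morphed heatmaps at float16 to bound memory
(the 500-frame default scene needs ~330 MB); fitting always accumulates
from the full-precision morphs before downcasting, and decoding from
the cache is argmax-robust to the ~1e-3 relative float16 error.

### Why it corrects isolated errors — and when it cannot

On a clean neighbour, the morphed heatmap peaks at the target's true
location (the flow carries the blob's displacement). A single-frame
failure contributes one wrong peak against `2f` truthful ones; with
anything close to uniform weights the truthful mass dominates the
argmax. When errors persist across the whole window (run length
`>= 2f+1`), no truthful evidence remains and aggregation reproduces the
error — the documented limitation, asserted in the tests only as "no
catastrophic degradation" (at most 2x the base error).

## Multi-view correction

Two perpendicular views sharing the x-axis (side/bottom mirror
geometry): the reliable view's x-coordinate arbitrates between
candidate peaks of the other view's heatmap. Candidates are local
maxima of the Gaussian-smoothed grid (`smooth_sigma` **3 px**,
`min_rel` **0.1** of the global maximum — both package conventions),
strictly greater than all 8 neighbours; the global maximum is always a
candidate. The corrected location is the candidate minimising
`|x - x_ref|`; ties prefer the higher score, then the smaller row-major
index. The original location is kept when it already matches the
reference at least as well, so correction never increases
`|x_side - x_ref|`. The supplied reference locations are used as-is
(raw argmax or aggregated output, whichever the caller provides).

## Preprocessing

* Split: 3:1:1 train/validation/test by largest-remainder
  apportionment, seeded shuffle; optional video-level grouping (greedy
  fill of the most under-target split) so no video spans two splits.
* Rotation: expanded canvas (no crop), black padding, bilinear image
  interpolation; annotation coordinates mapped by the exact affine
  matrix; box sizes unchanged. Random angles uniform in (-10°, +10°)
  by default.
* Flips: about the x-, y-, or both axes, probability 0.5 per admissible
  axis; an optional involutive swap map exchanges bilaterally symmetric
  keypoint names (default: none).
* Resize: area-average (local-mean) when shrinking, bilinear when
  enlarging; coordinates and box sizes scaled linearly
  (`x' = x * out_w / W`).

## Synthetic benchmark

The simulator renders P Gaussian blobs (sigma 2 px, amplitude 0.6 over
a 0.2 background) on a 96x96 frame with fixed smooth texture
(amplitude 0.08, needed by the flow) plus per-frame noise (sigma 0.01).
Keypoint p follows `x(t) = x0 + A sin(2 pi t / T + phi_p)` with
A = 12 px, T = 60 frames and staggered phases — out-of-phase limb-like
motion with inter-frame displacements up to ~1.3 px (≈5 px across the
half-window), comfortably inside the flow regime. Occlusion episodes
cover the blob with a rectangle panel while the true track continues.
Annotations carry a fixed square box of side `4 * blob_sigma` = 8 px.
All randomness derives from the single scene seed.

Standard scenarios (500 frames, P = 4, except `static` at 120 frames —
enough for edge-window and equality checks on a scene with no temporal
structure):

* `static` — zero motion, clean mock: aggregation must equal the base.
* `gait` — the motion scene, clean mock.
* `isolated-errors` — gait + mock failures with probability 0.15,
  displacement 40 px, run length 1 (runs separated by at least one
  clean frame, so errors are strictly isolated; the realized per-frame
  failure rate is slightly below 0.15 because of that separation).
* `error-runs` — failures persist 9 frames, spanning the default
  window.
* `two-view-swap` — paired views; side-view failures are x-displaced
  with a 0.6-height truthful secondary peak, bottom view clean.

The mock base predictor re-renders a Gaussian peak (sigma 2 px) at the
true location jittered by 0.5 px; failures displace the peak by a fixed
distance in a per-run random direction. It reproduces the *failure
statistics* a trained network exhibits around temporary occlusions, not
its appearance model: passing these tests shows the temporal and
multi-view machinery corrects the failure modes it targets, not that
any particular network reaches a particular accuracy on real animals.
Real data add appearance drift, correlated multi-keypoint failures,
non-rigid deformation and camera noise that the simulator does not
model.

## Problem sizes

The shipped tests and the acceptance script run the 500-frame, 4-keypoint,
96x96 scenarios (seeds 0–4 for the isolated-error condition, seed 0 for
the run-length condition) and complete in a few minutes on one CPU;
larger scenes scale linearly in frames and window length.

## Known limitations

* The deep base model is deliberately out of scope: its structural
  hyperparameters are parsed and validated as configuration, and any
  trained network can be plugged in behind the predictor contract.
* Flow-based morphing assumes brightness constancy between nearby
  frames; rapid lighting changes violate it.
* The temporal module cannot correct error runs spanning the window;
  increasing `f` or `s` widens coverage at the cost of flow accuracy
  over longer baselines.
* Multi-view correction requires the truthful location to survive as a
  candidate peak; if the heatmap carries no secondary mode at the true
  location, the correction keeps the (wrong) original prediction.
* The correction handles exactly two views; triangulation across three
  or more views is out of scope.
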