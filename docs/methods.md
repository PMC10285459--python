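# Methods

## Box representation and geometry

All rotated boxes use the long-edge convention: `(x, y, w, h, θ)` with
`w ≥ h > 0` and `θ ∈ [−π/4, 3π/4)`, where `θ` is the clockwise angle (in
image coordinates, y down) between the long edge and the x-axis. A
rectangle is invariant under a half turn, so angles live on a circle of
period π; `normalize_angle` wraps with `(θ + π/4) mod π − π/4` and
`canonicalize` additionally swaps edges (adding π/2) when `w < h`. Boxes
with an edge below 1e−6 px are rejected at construction; the spec of the
detection task never produces degenerate rectangles and the clipping code
assumes positive area.

Skew IoU is computed exactly: one corner quadrilateral is clipped against
the other with Sutherland–Hodgman (collinearity tolerance 1e−9 via the
signed-side test), and the intersection polygon's area comes from the
shoelace formula. This equals triangulating the intersection over its
vertices; clipping was chosen for robustness and testability. Degenerate
contact (shared edge or vertex) yields area 0 and IoU 0 — no sign-noise
branches. The pair is ordered canonically before clipping so
`skew_iou(a,b)` and `skew_iou(b,a)` are bitwise equal. Two independent
oracles check the implementation: Monte-Carlo rasterization (uniform
samples over the joint extent; with 10⁶ samples the estimate agrees to
within 0.01 on random pairs) and, in the test suite only, shapely's
polygon intersection.

A vectorised one-against-many clipper (fixed 8-vertex buffers — a convex
quad clipped by a convex quad has at most 8 vertices) drives the hot
paths: greedy rotated NMS and evaluation matching. NMS prefilters pairs
by axis-aligned extents (disjoint extents ⇒ IoU 0), breaks score ties by
ascending index, and supports an early stop at `max_keep` survivors,
which is identical to truncating the full result.

## Annotation dialects

roLabelImg stores `robndbox/{cx,cy,w,h,angle}` with the angle in radians,
clockwise, in `[0, π)` for the stored `w` edge. On read every box is
canonicalized into the long-edge convention; on write the angle maps back
via `θ mod π`. Round trips are lossless to float precision (`repr`
serialization). labelImg/PASCAL-VOC uses `bndbox/{xmin,ymin,xmax,ymax}`.
Deriving the horizontal dataset replaces each rotated instance with its
circumscribed axis-aligned box — count preserved, area never decreased.
Boxes crossing the image border are kept unclipped by default (truncated
scars are legitimate instances; the horizontal derivation likewise does
not clip); an optional clip refits the smallest enclosing box at the
original angle to the clipped corners.

Statistics: mean instances/image reported to 2 decimals; aspect-ratio
histogram over bins {[1,2), [2,3), [3,5), [5,8), [8,∞)}; angle histogram
over 8 equal bins of `[−π/4, 3π/4)`. Density subsets: 1–9 sparse, 10–19
medium, ≥20 dense; empty images stay unlabeled.

## Synthetic scenes

The generator emulates the statistical structure of leaffolder-damage
survey imagery, not its radiometry: a low-pass-filtered green texture
(Gaussian-smoothed noise around canopy green, σ = 3 px, ±25% modulation),
pale yellow-white streaks (alpha-blended cores filling their annotated
box, per-instance brightness jitter), aspect ratios from a mixture with
P(w/h > 5) = 0.55 (slender component 5 + Exp(3), compact component
U(1.5, 5)) matching "slightly over half above 5", orientations uniform on
`[−π/4, 3π/4)`, lengths U(40, 120) px by default, and a crossing
probability (default 0.2) that seeds an instance near an existing one.
Density names draw counts uniformly from {1..9}, {10..19}, {20..35}.
Sunlight mode multiplies a linear ramp (up to +40%) in a random direction
and adds 2–4 Gaussian specular blobs — a stand-in for an
illumination-affected subset that has no quantitative definition.

Everything is a pure function of `(SceneSpec, seed)`; datasets spawn
per-scene seeds from the master seed through `SeedSequence`, so manifests
are byte-identical across runs. What passing tests on these scenes show:
the geometry, assignment, training and evaluation code paths work and the
demo model can learn salient elongated targets. What they do not show:
robustness to real-field nuisance structure (occlusion by leaves, bent
scars, specular leaf highlights, camera variation).

## Anchors and adaptive sample selection

Three horizontal anchors per cell (ratios 0.5/1/2 — the 0.5 anchor
canonicalizes to θ = π/2) on pyramid levels P2–P6 with strides 4–64 and
areas 32²–512²; centers at `((i+0.5)s, (j+0.5)s)`; grids `ceil(W/s) ×
ceil(H/s)`.

Per ground truth, the `n = 9` center-closest anchors on each level are
candidates (`n` is not stated for this selection scheme in the source
description; 9 is the value the adaptive-selection literature uses, and
it is configurable). The positive threshold is `mean + population-std` of
the candidates' skew IoUs. A ground truth whose candidates all fall short
claims its best-overlap candidate — without this fallback the mean+std
rule cannot guarantee every instance a positive. Anchors wanted by
several ground truths go to the larger IoU (ties to the lower index); a
ground truth stripped bare by that resolution reclaims its best candidate
whose owner keeps ≥ 2 positives. Candidate IoUs use the scalar pairwise
path so threshold comparisons are bit-stable against the explicit-loop
reference implementation the tests compare against, label for label.

Batches are strictly 1:1 positive:negative up to N = 256 per image (the
batch shrinks below 256 when positives are scarce rather than padding
with negatives; the loss divides by the actual batch size).

## Delta coding and loss

Encoding follows the five-offset form exactly (`d_θ = θ_t − θ_a`, raw
difference); decoding inverts it and renormalizes the angle by
`(d_θ + θ_a + π/4) mod π − π/4`, then canonicalizes. An optional
`wrap_angle` toggle regresses the short way around the angular boundary;
it is OFF by default to keep the printed coder verbatim. Decoded edges
are clamped at 10⁶ px with a warning (runaway `exp` early in training).
The loss applies one shared 1/N factor to the classification sum (over N
samples) and the smooth-L1 regression sum (over Np positives) — as
printed, though most frameworks normalize the two terms separately. RPN
classification is sigmoid-binary (the per-cell score count W·H·3·1
implies one logit per anchor); the second-stage head is a 2-way softmax
(`Linear(1024, 2)`).

## Rotated RoI alignment

Proposals project to feature scale with edges divided by the stride and
centers divided then **floored** — kept as specified even though the
floor introduces ≤ 0.5-cell quantization; `floor_centers=False` exists
for ablation. Bin (m, n) of the k×k grid (k = 7 default; m runs along
the long edge) draws l = 4 samples at 2×2 sub-bin centers in the local
frame `[0, w_f] × [0, h_f]`, maps them through the rotation about the
region center, and reads the map by bilinear interpolation anchored at
integer cell centers, zero outside the map; the bin value is the sample
mean. Sub-bin *centers* (not corners) and l = 4 are package choices where
the operator description leaves them open. The horizontal RoIAlign
baseline shares the identical sampling scheme with θ = 0, so the two
agree to 1e−6 on axis-aligned proposals.

## Detector and demo trainer

Backbones: a standard ResNet-50 trunk (batch-norm affine parameters are
trainable and counted; running statistics are fixed buffers) and a
normalization-free "tiny" 4-stage CNN (channels 16/32/64/128, two 3×3
convs per stage) that emits the same 5-level pyramid for CPU-fast tests.
FPN: 1×1 laterals, nearest ×2 top-down sum, 3×3 output convs, P6 by
stride-2 subsampling of P5 (no parameters). The full-size graph counts
41,349,977 trainable parameters (41.35 M).

Proposal pipeline: per level, sigmoid scores, top-2000 pre-NMS, rotated
NMS at 0.8, then aggregation and global score sort capped at 2000
(training) / 1000 (inference); final detections filter at score 0.05 and
NMS 0.1. None of these caps/thresholds is stated by the source
description; they are conventional two-stage rotated-detector defaults
and all configurable (the tiny configuration shrinks them for speed).
Second-stage training assignment: skew IoU ≥ 0.5 positive, 512 samples
at 1:3 pos:neg (64 for tiny); ground-truth boxes join the candidate pool
so the head sees well-aligned positives early — standard RCNN trainer
practice, not part of the published method. Proposals are pooled from the
level `clamp(⌊log₂(√(wh)/56)⌋ + 2, 2..5)` (strides 4–32).

Prediction layers initialize near zero (std 0.01 for classification and
RPN regression, 0.001 for the refinement regressor) so initial proposals
coincide with their anchors and refinement starts at the identity; hidden
layers use He initialization. All weights derive from the config seed.

The network is defined on a small built-in reverse-mode autodiff
(`rotdet.nn`): single-image im2col convolution, max pooling, nearest
upsampling, dense layers, the detection losses, and a rotated-RoI pooling
op whose gradient flows into the feature map (not the proposal
coordinates). Every op is verified against central finite differences.

Demo training: one image per step, SGD with momentum 0.9, lr 2e−3
(selected for stable convergence of the reduced configuration), dropped
10× at 2/3 and 11/12 of the run — the shape of a 36-epoch schedule with
decays at epochs 24 and 33, scaled down. The default problem size (the
package's CPU-scale demonstration setting) is 192×192 scenes, 50 training
images, 200 iterations; under it, held-out AP@IoU0.5 on sparse scenes
rises from 0.0 (untrained) to ≈ 0.25–0.32. Deterministic for fixed seed
and dataset.

## Evaluation

Greedy per-image matching in descending score order; a detection claims
its highest-overlap unmatched ground truth (ties to the lower index) if
the overlap meets the threshold, under skew IoU or skew IoF (overlap /
detection area — since IoF ≥ IoU pairwise, IoF-AP dominates IoU-AP at
equal threshold). AP integrates the monotone precision envelope over
recall at every distinct score (all-points interpolation — the standard
reading of the continuous integral; an 11-point variant sits behind a
flag, and the interpolation choice is documented rather than fitted
because the reference results are not desk-reproducible). A brute-force
evaluator that re-matches from scratch at every score cutoff serves as
the independent cross-check. Single class throughout.

## Known limitations

- Axis-anisotropic image resizing maps a rotated box to a parallelogram;
  the detector approximates the result with the box spanned by the
  transformed edge vectors (exact for uniform scaling, which is the only
  case the bundled pipelines produce).
- The demo trainer runs batch size 1 and a normalization-free backbone;
  it demonstrates learnability, not competitive accuracy.
- No masks or curved-scar geometry; heavily occluded or bent symptoms
  are out of scope.
- The full-size ResNet-50 path is built and counted (and can run
  inference) but is far too slow to train in NumPy; training-scale
  results are only produced with the tiny configuration.
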