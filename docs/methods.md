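# Methods

`weedspot` implements a multi-modal detection pipeline for weeds in wheat
fields from paired RGB and depth imagery. This note records the models and
procedures, the parameters that matter, and the choices made where the
design was genuinely open.

## Problem setting

Grass weeds (e.g. *Alopecurus*, *Poa*, *Bromus*) have narrow leaves that
look almost identical to wheat in color imagery, which is why RGB-only
detectors miss them; broad-leaf weeds are visually distinct. Depth imagery
from a top-down RGB-D rig adds the geometric cue that separates grass
weeds from the canopy: plant height. The pipeline therefore (1) aligns and
repairs the depth channel, (2) recodes it into a geometry-bearing
three-channel image, (3) runs a three-branch detector over the RGB image
and the recoding, and (4) fuses the branch decisions with scalar weights.

## Depth preprocessing

**Alignment.** The two sensors have different optical centres, so depth
must be resampled into the color camera's pixel grid before labels can be
shared across modalities. Each valid depth pixel is deprojected with the
depth intrinsics (`X = d * K_d^-1 (u, v, 1)^T`, pixel-centre convention,
0-based `(column, row)`), moved by the rig extrinsics `X' = R X + t`
(mm), reprojected with the color intrinsics and splatted to the nearest
output pixel. Collisions resolve by z-buffer: the smaller depth (nearer
surface) wins, which is what the color camera would actually see. Metric
values are moved, never interpolated; unmapped output pixels stay invalid.
Nearest-pixel splatting bounds the geometric error at 0.5 px, which is
below the annotation granularity this pipeline cares about.

**Hole filling.** Consumer depth sensors drop pixels (value 0) under bad
lighting, low-reflectance surfaces and occlusion shadows. Holes are filled
by the median of the valid pixels in a window, iterated with a growing
window (3, 5, 7, ...) until every pixel is valid. The median guarantees
filled values stay inside the range of observed depths, never modifies an
originally valid pixel, and makes the operation idempotent. At smooth
surfaces the filled values track the underlying geometry to within the
sensor noise; at depth discontinuities the *true* value of an occluded
pixel is ill-defined (it depends on which surface the pixel "belongs" to),
so accuracy claims are only meaningful away from edges and are tested that
way.

## PHA recoding

A raw depth image is a monotone distance map — one channel, low contrast,
poor input for a convolutional network built for three correlated texture
channels. The recoding replaces distance with three geometric quantities,
quantised to 8 bits:

* **Phase** `phi = (d mod 2*pi*l) / l` in `[0, 2*pi)`. Active-stereo
  sensors derive depth from a periodic code with uniqueness range
  `2*pi*l`; folding the depth back into that range restores
  high-frequency structure. The sensor's true `l` is not public, so `l`
  is a parameter. Default `l = 64` gives a ~402 mm range — at least two
  wraps over a 700 mm camera height plus canopy — which keeps visible
  structure in the channel. The interval is half-open; a depth exactly at
  a wrap boundary maps to 0.
* **Height above ground** `H = d_max - d`, with `d_max` the maximum
  distance in the image (per-image by default; a fixed global override
  exists for cross-image comparability). Ground is 0, plants positive.
* **Angle with gravity** `theta = arccos(n . g)` in degrees, `[0, 180]`,
  between the per-pixel surface normal and the estimated gravity
  direction. Normals are total-least-squares plane fits over a
  `normal_window` (default 5 px) neighbourhood of deprojected points,
  oriented toward the camera; the angle is deliberately not folded to
  `[0, 90]` so up- and down-facing surfaces stay distinguishable.

Quantisation uses fixed linear maps (`phi * 255 / 2pi`, `H * 255 / d_max`,
`theta * 255 / 180`), channel order (P, H, A). The detector consumes the
8-bit raster, structurally interchangeable with RGB. For like-for-like
information comparisons, raw depth is rendered to 8 bits with the same
convention (`255 * d / d_max`); on synthetic scenes the PHA image's mean
histogram entropy exceeds the rendered depth's (≈6.2 vs ≈5.5 bits), which
is the motivation for recoding in one number.

**Gravity estimation.** Ground pixels have normals parallel to gravity;
standing stems and leaf edges have normals perpendicular to it. Starting
from the camera's down axis (+z for a near-nadir rig), each iteration
classifies normals into a parallel set (within `gravity_angle_threshold`,
default 20°, of ±g) and a perpendicular set (within the threshold of the
plane orthogonal to g), then re-estimates g as the largest-eigenvalue
eigenvector of the scatter-difference matrix
`M = Σ_par n nᵀ − Σ_perp n nᵀ`, i.e. the minimiser of
`Σ_par sin²θ + Σ_perp cos²θ`. This is the semantically consistent
objective (parallel normals pull g toward themselves, perpendicular
normals push it away); the transposed form — minimising
`Σ_par cos²θ + Σ_perp sin²θ`, the smallest eigenvector — appears in some
writeups and is available via `gravity_objective="printed"`, but it is
inconsistent with the set labels and does not recover ground truth, so it
is not the default. Iteration stops when g moves < 0.1° (typically 3–5
iterations). The sign is fixed so g points along the camera's down axis.
On 20 synthetic scenes at 128×128 with ≤5° tilt and 2 mm noise the median
angular error is ≈1.3°; 96 px scenes are too coarse for the 5 px fit
window and degrade to ≈2.6°, a resolution artefact worth knowing about.

## Synthetic scenes

The generator emulates the statistical structure of a top-down survey of
a weedy wheat field so the full pipeline is testable offline. It renders
exact pinhole geometry: the ground plane is perpendicular to a gravity
vector tilted up to 5° from the optical axis (so gravity estimation is
non-trivially exercised), at 700 mm camera height; a surface point at
height h above ground seen through pixel ray r has z-depth
`(700 − h) / (g·r)`. The canopy is wobbly wheat rows at 80–200 mm; grass
weeds are thin strokes at 250–400 mm whose colors are drawn from the
*same* green-hue family as wheat (RGB-ambiguous by construction,
height-distinct); broad-leaf weeds are lobed rosettes at 120–280 mm in a
distinct blue-green. Sensor artefacts: Gaussian depth noise (default
2 mm) and invalid pixels placed with probability proportional to the
local depth gradient (holes concentrate at occlusion edges, as real
shielding losses do) at an expected fraction `hole_fraction`. Weed
strokes are floored at ~5 px thickness so box annotations remain
meaningful at small raster sizes; at the default 500×500 the fractional
width dominates and the floor is inactive.

What the generator does **not** emulate: photorealistic texture, leaf
occlusion layering, specularity, real sensor noise statistics
(non-Gaussian, range-dependent), or growth variation. Tests passing on
these scenes demonstrate the pipeline's mechanics — geometry, learning,
fusion, metrics — not field-level accuracy.

Augmentation is restricted to right-angle rotations and flips applied
consistently to rasters, masks and boxes; arbitrary-angle rotation is
excluded to keep boxes axis-aligned.

## Detection network

Three branches share a two-stage detector design (Faster R-CNN-style:
region proposal network over anchors, then an RoI head refining class
scores and boxes):

* **RGB-specific** and **PHA-specific** branches detect from their
  backbone's final (stride-16) feature map.
* The **correlated** branch builds a multiscale *hyper feature* per
  modality from the feature maps after backbone blocks 1, 3 and 5: the
  shallow map is max-pooled 4× down, the deep map deconvolved 4× up
  (learned, kernel = stride so the upsampling is exact), all three
  concatenated at stride 4, response-normalised across channels and
  projected by a learned 1×1 convolution. The two modalities' hyper
  features are fused by elementwise (Hadamard) product. The projection is
  linear — a ReLU there would zero about half of each factor and the
  product of two sparse maps is almost everywhere zero — and the product
  is renormalised because multiplication squares the dynamic range.

The RGB and PHA backbones share weights by default (one parameter set
serves both modalities; the shared module is literally the same Python
object, so updates coincide by construction). Backbones are configurable:
`vgg16` is the classic 13-conv-layer stack; `tiny` keeps the 5-block
stride pattern (1, 2, 4, 8, 16) at widths (8, 16, 16, 24, 32) and trains
in about a minute on one CPU. The network substrate is a small
reverse-mode autodiff engine over numpy (im2col convolution,
non-overlapping pooling/deconvolution, RoI max pooling, stable
classification losses), written for this package.

**Anchors and supervision.** Three scales × three ratios per location,
with ratios (0.33, 1, 3) because grass-weed boxes are extremely
elongated. Positives are anchors with IoU > 0.7 with a ground-truth box
*plus*, for every ground-truth box, its best-overlapping anchor (claimed
uniquely, so overlapping ground truths each keep a positive); negatives
fall below IoU 0.3; the rest are ignored. The RPN loss is
`L = (1/N_cls) Σ L_cls(p_i, p_i*) + λ (1/N_reg) Σ p_i* SmoothL1(t_i − t_i*)`
with log loss for classification, the classification term normalised by
the sampled mini-batch size and the regression term by the number of
anchor locations, λ = 10 so the two terms are comparably scaled. Box
deviations use the standard parameterisation `t_x = (x* − x_a)/w_a`,
`t_w = log(w*/w_a)` (and y/h analogously); Smooth L1 is `0.5x²` for
`|x| < 1`, else `|x| − 0.5` — continuous and C¹ at the knee. Proposal
NMS uses IoU 0.7; final per-class NMS 0.3; detection score floor 0.05.

**Training.** SGD with momentum, one image per iteration, all three RPNs
supervised simultaneously with the same boxes, plus per-branch RoI head
losses (softmax cross-entropy + class-wise Smooth L1 on normalised
deltas). Defaults follow the reference schedule: initial learning rate
0.001, momentum 0.9, weight decay 0.0001.

Small-image runs need careful conditioning, all standard practice:
prediction layers get tiny-variance init (so early proposals coincide
with their anchors instead of being scattered by random deltas), the
objectness bias starts at −2 (background prior), head box-deltas are
normalised by std (0.1, 0.1, 0.2, 0.2), ground-truth boxes plus jittered
copies are added to the head's training RoIs so it learns to *refine*
imperfect proposals, positive anchors are oversampled (≤4×) and the RPN
anchor batch shrinks to 32 when the image is small (a 256-sample batch on
a 64 px image would be almost all background). Inputs are standardised to
`(x/255 − 0.5)/0.25`.

On eight 64×64 synthetic pairs the tiny detector overfits within 500
iterations to training-set recall ≥ 0.9 at IoU 0.5 with IoG > 90% — the
sanity floor showing the full stack learns, not a field benchmark.

## Decision-level ensembling

The ensemble score is `G(x) = α g_RGB(x) + β g_PHA(x) + (1−α−β) g_corr(x)`
with `α, β ≥ 0`, `α + β ≤ 1`. Branch outputs are box lists, so the
combination is realised by clustering: same-class detections across
branches are processed in descending raw-score order; a detection joins
the best-overlapping cluster with IoU ≥ `cluster_iou` (default 0.5) that
lacks a member from its branch, else founds a new one. A cluster's fused
score is the weighted sum of member scores (absent branches contribute
0); its box is the mean of member boxes weighted by `branch_weight ×
score`, so at a simplex corner the ensemble reduces *bit-exactly* to a
single branch (single-contributor clusters return the member box
unchanged, zero-weight clusters are dropped). Box averaging can be
disabled, in which case the highest-weighted member's box is kept.

Weights are chosen by exhaustive search over the feasible grid (step
0.05: 231 points), scoring validation mAP by default or IoG via a flag;
ties break toward smaller α then smaller β, making the result independent
of image ordering. Note that mAP depends on score *ranks* only, so a
validation set where other branches are empty ties across all α > 0 and
the tie-break returns the smallest feasible α; separating the corner
requires a case where wrong branches actively hurt (e.g. misaligned
member boxes dragging the fused average).

## Evaluation

* **AP / mAP**: greedy score-descending matching (each ground truth
  consumed at most once; a detection is a true positive iff it reaches
  the IoU threshold, default 0.5, against an unmatched same-class box),
  then the area under the monotone right-envelope precision–recall curve
  (all-point interpolation; an 11-point variant is available). mAP is the
  unweighted mean over the two classes; a class with no ground truth has
  undefined AP and is excluded with a warning.
* **IoG (intersection over ground truth)**: the pixel area of the
  intersection between the union of above-threshold detection boxes and
  the union of ground-truth boxes, divided by the ground-truth union
  area, aggregated over the dataset by summing areas before dividing.
  IoG measures *coverage* of labelled weed area and is insensitive to how
  an annotator split clustered vegetation into boxes — the reason it
  complements AP for this task. It is class-agnostic by default
  (coverage is about area, not identity); a per-class variant exists.
  The detection score cutoff defaults to 0.3 — below typical confident
  detections, above the 0.05 output floor.

## Numerical and degenerate-input choices

* Boxes are 0-based half-open `[x1,x2)×[y1,y2)` everywhere in memory;
  Pascal VOC's 1-based inclusive convention exists only at XML
  boundaries. Invalid depth sentinel is 0 mm in 16-bit PNGs.
* NMS and matching sort descending with stable index tie-break, so all
  results are deterministic.
* Gravity estimation errors out if no normals classify (threshold too
  tight) and returns the best iterate with a `converged=False` flag if
  the 0.1° tolerance is not reached within `max_gravity_iters`.
* Rank-deficient normal neighbourhoods inherit the nearest
  well-conditioned estimate (Euclidean distance transform).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; fixed seeds reproduce scenes bit-for-bit
  and training loss logs exactly.

## Problem sizes used in verification

Desk-scale checks use 128×128 scenes for geometry (gravity, entropy,
alignment, hole filling; 20 scenes where a distributional claim is made)
and eight 64×64 pairs with the tiny backbone for learning checks. These
sizes were chosen as the smallest at which each property is cleanly
expressed — normals need a few pixels of support, boxes need ~5 px
features — and everything runs in minutes on one CPU.

## Known limitations

* The synthetic scenes are statistically, not photometrically, realistic;
  no claim about field accuracy follows from them.
* The `vgg16` backbone is provided and tested for shape/contract but is
  not practical to train in this package's CPU budget; no pretrained
  weights are downloaded.
* Lens distortion, rolling shutter and sensor-specific noise models are
  out of scope; alignment assumes ideal pinholes.
* The phase channel's `l` is a free parameter, not the sensor's true
  uniqueness range.
* Ensemble weights are searched, not learned; gradient-based weight
  assignment is future work.
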