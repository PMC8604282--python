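# weedspot

Multi-modal RGB-D detection of weeds in wheat fields.

Grass weeds (*Alopecurus aequalis*, *Poa annua*, *Bromus japonicus*, ...)
have narrow leaves that are nearly indistinguishable from wheat in color
imagery, which is why RGB-only detectors systematically miss them. A
top-down RGB-D camera adds the cue that does separate them: geometry.
`weedspot` implements a complete pipeline for exploiting it:

1. **Depth preprocessing** — alignment of the depth raster into the color
   camera's pixel grid through the two-sensor pinhole model
   (deproject → rigid transform → reproject, z-buffered splatting), and
   median-based hole filling of sensor dropouts.
2. **PHA recoding** — the single depth channel becomes a three-channel
   geometric image: **P**hase `φ = (d mod 2πl)/l`, **H**eight above
   ground `H = d_max − d`, and **A**ngle with gravity
   `θ = arccos(n·g)`, where the gravity direction `g` is estimated from
   the surface-normal field itself (ground normals are parallel to
   gravity, standing leaves perpendicular; `g` solves
   `min_{‖g‖=1} Σ_{n∈N₁} sin²θ(n,g) + Σ_{n∈N₂} cos²θ(n,g)` by an
   iterative eigen-decomposition). The result is structurally an RGB-like
   image and measurably richer than raw depth (≈6.2 vs ≈5.5 bits of
   histogram entropy on synthetic scenes).
3. **Three-branch detection network** — RGB-specific, PHA-specific and
   RGB-D-correlated branches, each a two-stage detector (region proposal
   network over anchors + RoI head). The correlated branch fuses
   multiscale *hyper features* (backbone blocks 1, 3, 5 resampled to
   stride 4) from both modalities with a Hadamard product
   `f_corr = f_RGB ∘ f_PHA`. RPN supervision follows the standard
   multi-task loss
   `L = (1/N_cls) Σ L_cls(p_i, p_i*) + λ (1/N_reg) Σ p_i* SmoothL1(t_i − t_i*)`.
   The RGB and PHA backbones share weights. Backbones: `vgg16`, or a
   `tiny` variant with the same stride pattern that trains in about a
   minute on one CPU. (The network runs on a small numpy autodiff engine
   included in the package — no GPU framework required.)
4. **Decision-level ensembling** —
   `G(x) = α·g_RGB(x) + β·g_PHA(x) + (1−α−β)·g_corr(x)` with
   `α, β ≥ 0, α+β ≤ 1`, realised by IoU-clustering of same-class boxes
   across branches; `(α, β)` chosen by exhaustive grid search (step 0.05,
   231 feasible points).
5. **Evaluation** — per-class average precision (area under the
   interpolated precision–recall curve), mAP, and **IoG** (intersection
   over ground truth): the fraction of labelled weed *area* covered by
   detections, robust to how annotators split clustered vegetation into
   boxes.

Field data of this kind is not publicly deposited, so the package ships a
first-class synthetic scene generator (`weedspot.synthetic`) that emulates
the survey geometry — tilted ground plane, wheat rows, RGB-ambiguous but
tall grass weeds, distinct broad-leaf rosettes, edge-concentrated depth
holes — with exact ground truth for every quantity the pipeline estimates.

## Worked example

`examples/03_train_tiny_detector.py` renders eight 64×64 scenes, trains
the tiny three-branch detector from scratch (500 SGD iterations,
lr 0.001, momentum 0.9, weight decay 0.0001), fuses the branches at equal
weights and scores the training set:

```
loss: 6.25 -> 2.04 over 500 iterations
training-set recall@IoU0.5: 15/16 = 0.94
mAP: 92.2%  IoG: 91.7%  per-class AP: {'grass': 84.4, 'broadleaf': 100.0}
```

Recall counts planted weed boxes recovered at IoU ≥ 0.5; IoG is the
fraction of planted weed area covered by confident detections. Recovering
essentially all of its own training boxes is the end-to-end sanity floor
for the learning stack, not a field benchmark. The other examples cover
scene generation and recoding (01), metric alignment (02), ensemble
weight search (04) and the full on-disk pipeline (05).

The same stages are scriptable from a shell:

```bash
weedspot generate --out scenes --n 16 --size 64 --seed 7
weedspot recode --depth scenes/depth --rig scenes/rig.yaml --out pha
weedspot train --data scenes --pha pha --out weights.npz --iterations 500
weedspot detect --weights weights.npz --rgb scenes/rgb --pha pha --out dets
weedspot ensemble --pred dets/rgb.jsonl dets/pha.jsonl dets/corr.jsonl \
    --alpha 0.4 --beta 0.3 --out fused.jsonl
weedspot evaluate --pred fused.jsonl --ann scenes/ann
weedspot run --out run1 --n 16 --size 64 --seed 7   # all of the above
```

## Layout

```
src/weedspot/     library (synthetic, rgbd_io, pha, network, training,
                  ensemble, evaluation, pipeline, cli, nn substrate)
examples/         one narrative script per capability
tests/            pytest suite, including acceptance-level properties
docs/methods.md   models, parameters, design decisions, limitations
```
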