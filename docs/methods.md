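# Methods

This note records the model, the numerical and design choices behind the
implementation, what the synthetic data does and does not emulate, and the
known limitations.

## Model

The detector is a faithful re-creation of the anchor-free YOLOX-L layout:
a CSPDarknet backbone (base width 64, CSP depths 3/9/9/3 scaled by the
depth multiplier), a PAN neck fusing the stride-8/16/32 feature maps, and
per-scale decoupled heads (1×1 stem to 256·w channels, two 3×3 convs per
branch, 1-channel IoU/objectness and 4-channel box regression on the
regression side). All convolutions are conv(no bias) + batch-norm + SiLU.
Box decoding is anchor-free: at grid cell (gx, gy) with stride s the
regression output (tx, ty, tw, th) means centre ((tx+gx)·s, (ty+gy)·s) and
size (e^tw·s, e^th·s); the detection score is sigmoid(cls)·sigmoid(obj).

Modifications relative to the stock layout:

* **Stem**: a single k=6, s=2, p=2 convolution replaces the Focus block.
  Both map 3×H×W to 64·w×H/2×W/2 with 108 weights per output channel, so
  geometry, parameters, and multiply-accumulates are identical.
* **SPPF**: the {5, 9, 13} parallel max poolings become three chained k=5,
  stride-1 poolings. Because max windows nest (two chained 5-windows span
  9, three span 13), the four concatenated maps are exactly equal to the
  classic pyramid's; the unit tests assert bitwise equality.
* **CBAM** is inserted once per head, after the 1×1 stem, on the
  256·w-channel features (reduction 16). Channel attention:
  sigmoid(MLP(avgpool) + MLP(maxpool)) with a shared C→C/16→C MLP; spatial
  attention: sigmoid(conv7×7([mean_c; max_c])). Each scale has its own
  CBAM instance. Head placement (rather than on the neck outputs) keeps
  the attention where the detection and count branches share features and
  reconciles the inference-parameter total with the published 54.2 M; at
  neck placement the larger P4/P5 widths push the total to 54.3 M.
* **Count head** (training only): per scale, a decoupled branch of two 3×3
  convolutions at head width followed by a 1×1 compression to one channel;
  the three maps are flattened and concatenated — 128²+64²+32² = 21 504
  elements at 1024² input — then fused by Linear(21 504 → 956) + SiLU +
  Linear(956 → 300). The final layer is zero-initialized so the initial
  count distribution is exactly uniform and the initial count loss is
  exactly log 300. The published description fixes the compression,
  flatten, and fully-connected fusion but not the widths; the two free
  widths here (the conv branch mirroring the cls/reg branches, and the
  hidden size 956) are pinned by the published parameter and FLOP totals:
  the branch convolutions account for the +50.9 G training-time FLOPs and
  the hidden layer brings total training parameters to 78.6 M. An FC-only
  head can match the parameter delta but adds only ~0.1 G FLOPs, so it is
  not consistent with the totals.

The count head exists only in the `mode="training"` graph. Building in
`mode="inference"` omits it entirely, and the tests verify that detection
outputs are bit-identical with and without it (and invariant to
perturbing its weights): the auxiliary task shapes shared features during
training but costs nothing at deployment.

## Losses

Count loss: log-softmax over the 300 count classes, then negative
log-likelihood at the true count (the number of ground-truth boxes),
averaged with unit class weights — i.e. cross-entropy. Counts above 299
are clipped to 299 with a warning. Total loss: 0.3·L_num + 1.0·L_YOLO.

Detection loss: positives chosen by SimOTA-style dynamic-k assignment —
candidates are anchors whose centre lies in a ground-truth box or within
2.5 strides of its centre; cost = cls BCE term + 3·(−log IoU) + a large
penalty outside the intersection of both priors; per-box k = clamp(sum of
top-10 IoUs, ≥1); conflicts resolve to the cheapest box. Loss = 5·(1−IoU)
on assigned regressions + BCE objectness over all anchors + BCE
classification at positives, all normalized by the positive count (the
5.0 regression weight follows the reference anchor-free design). A
fixed-radius centre assignment (`assigner="center"`, radius 1.5 strides,
nearest centre wins) is kept as a deliberately simple test mode; the
suite checks it against an independent loop-based brute-force evaluation
on 64×64 instances. No end-of-training L1 refinement phase is used.

## Training schedule

Two stages with AdamW (β = 0.9/0.999, ε = 1e-8, decoupled weight decay
0.01 applied only to ≥2-D parameters): stage 1 freezes backbone + neck and
trains the heads (detection branches, CBAM, count head) for 5 epochs at
lr 1e-3, γ 0.92/epoch, batch 8; stage 2 trains everything for 55 epochs at
lr 1e-4, γ 0.90, batch 2. Each epoch visits every training image exactly
once as the primary sample of one augmentation draw; Mosaic/MixUp
companions are drawn uniformly at random. Gradient norms are clipped at
10. Augmentation remains active through stage 2. One master seed derives
independent streams for initialization, data order, and augmentation;
full-precision runs are bit-reproducible and epoch-boundary checkpoints
resume exactly (asserted in the tests). The mixed-precision flag rounds
matmul/convolution operands through float16 with float32 accumulation; it
changes the smoke-run loss by well under 1 % and is excluded from
correctness tests.

## FLOP and parameter accounting

Parameters are exact integer totals over all weight elements. FLOPs are
measured by tracing a real batch-1 forward pass at the requested
resolution under a fixed convention: 2 FLOPs per conv/linear
multiply-accumulate (bias adds included), 1 FLOP per sigmoid/SiLU element,
batch-norm folded into its convolution, pooling/upsampling/concatenation
and elementwise attention rescaling free. The convention was pinned by
requiring the unmodified baseline (Focus stem, SPP, no CBAM, no count
head, 80-class COCO vocabulary — the configuration the published baseline
row describes) to reproduce 397.8 G at 1024²; it does (397.78 G), and the
same build reproduces the published 54.2 M baseline parameters. Under this
convention the modified 1-class inference model computes to 396.9 G and
the training model to 447.7 G. The published table prints 394.9 G and
445.8 G; the −2.9 G step it attributes to SPPF cannot arise from the
documented changes, since SPPF and the stem replacement are
multiply-accumulate-identical and CBAM only adds work. The deltas do
agree: count head = +50.8 G here vs +50.9 G published, +24.39 M vs
+24.4 M. The absolute 0.4–0.5 % gap on the two modified-model FLOP totals
is reported as computed, not adjusted.

## Synthetic scenes

The generator renders rotated filled ellipses (uniform length and width
ranges, random orientation, a mild along-axis intensity gradient) on a
dark background with additive Gaussian noise, placed along a horizontal
plant axis. `cluster_overlap` ∈ [0, 1] interpolates the placement scatter
from loose to tight packing; the suite checks that raising it raises mean
pairwise box IoU. Ground truth is exact by construction: each box is the
tight bound of its ellipse's rendered support, so the count equals the
number of rendered objects and every foreground pixel lies inside a box.
Defaults target the study-like regime (1024², Poisson mean 33, a preset
near 61, ≥60 % background pixels); counts are truncated at 299 to stay in
the count-class range. `easy_scene_config` is the deliberately benign
regime used for desk-scale parameter recovery: ≤ 8 large, bright,
non-overlapping ellipses on a 160² canvas.

What the generator does **not** emulate: stems and leaves, occlusion by
non-pod tissue, specular lighting, camera blur, pod-shape irregularity,
and annotation noise. Passing tests therefore demonstrate that the
implementation is internally correct and trainable — not that it attains
field-data accuracy; the published field results additionally require the
photographed datasets and GPU-scale training, which are out of scope here.

## Desk-scale problem sizes

The whole stack runs on one CPU with numpy, so the test suite uses scaled
problem sizes chosen as the smallest that still exercise every code path:
width ×0.25 / depth ×0.33 models, 64–160 px inputs, 8–64 images, and the
two-stage schedule shortened to 1 + 3 epochs with stage-2 batch 1 (keeping
the per-stage step counts meaningful at 64 images). For the recovery run
the stage-2 learning rate is 2e-3 rather than the published 1e-4: the
published rate fine-tunes a pretrained backbone, whereas the desk run
trains from scratch in ~200 steps. Counting at desk scale uses NMS IoU
0.45 and confidence 0.25; with a lightly trained model duplicate
detections overlap only moderately, and the tighter NMS removes them
without costing recall (both thresholds are configurable; 0.25/0.65 remain
the full-scale defaults).

## Numerical choices and degenerate inputs

* Internal box convention is 0-based, half-open, continuous; VOC XML's
  1-based inclusive integers are converted on read (xmin−1) and restored
  on write. Boxes with area ≤ 1 px² after conversion are dropped with a
  warning.
* log-softmax subtracts the row maximum; sigmoid/BCE use the exp(−|x|)
  formulations; decoded log-sizes are clipped to [−20, 10] before exp.
* Greedy highest-IoU matching and greedy NMS break ties by score order;
  elementwise max gradients route to the first operand on exact ties.
* R² is the squared Pearson correlation of predicted vs. true counts (the
  convention that makes the published R and R² tables consistent), not
  1 − SS_res/SS_tot. MAPE averages only over images with nonzero true
  count and errors if none exists; R² errors on zero-variance series.
* AP50 interpolation grids compare recall with a 1e-12 tolerance so grid
  points like 0.6000000000000001 do not exclude recall exactly 0.6.
* Mosaic drops clipped boxes retaining < 20 % of their area; the crop
  branch preserves a 2 px margin around the boxes' vertical span and, with
  no boxes, at least half the image height. MixUp uses a fixed 0.5 blend
  and unweighted label union.
* Batch-norm uses batch statistics in training mode (momentum 0.1);
  evaluation uses running statistics.

## Limitations

* Single class ("pod"); multi-class needs only config plumbing but is
  untested.
* numpy convolutions are orders of magnitude slower than a GPU framework;
  the full-size model is practical for accounting and single forwards,
  not for full-scale training.
* SimOTA is implemented per image with dense IoU matrices; fine at desk
  scale, quadratic in ground-truth count.
* Checkpoint resume is exact at epoch boundaries only.
* The Focus-stem baseline exists for accounting and equivalence checks; it
  is not wired into the training CLI.
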