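# Methods

## Scope and numeric core

`esadet` implements a complete one-stage detection pipeline for brain-tumor
MRI slices: the Enhanced Spatial Attention (ESA) block, the medium-width
YOLOv5-style detector graph with configurable ESA placement, the composite
detection loss, the data/augmentation pipeline, the evaluation protocol, a
synthetic phantom corpus, and training orchestration.

All tensor math, including backpropagation, runs on `esadet.nn`, a compact
reverse-mode autograd engine over float32 numpy arrays.  Convolutions are
im2col + BLAS matmuls; every primitive with a hand-written backward pass
(conv, max-pool, batch-norm, nearest upsampling, gather, BCE-with-logits)
is verified against central-difference numerical gradients in the test
suite.  This keeps the package importable anywhere numpy runs and keeps
every numerical step of the model inspectable.

## The ESA block

Three published formulations of the block exist (a sequential three-conv
chain producing the gate; a gated residual `F + alpha*(F o S)`; a parallel
multi-scale fusion without residual).  They are not algebraically
identical, so the package adopts as canonical the combination that
preserves the design intent of each: **parallel multi-scale descriptors**
(3x3 and 5x5 convolutions with bias, SiLU activation), **single-channel
sigmoid fusion** (1x1 convolution), and a **residual learnable scalar gate**
`alpha`.  The sequential chain is kept as the `sequential` variant
(channel bottleneck `r_seq = 16`, a common attention-reduction
convention).  The residual gate makes the block exactly the identity at
`alpha = 0`, which the ablation tests exploit.

No normalization layer is used inside ESA, so its parameter count has the
closed form

    (9*C*c3 + c3) + (25*C*c5 + c5) + (c3 + c5 + 1) + 1.

The internal widths are not published; `c3 = 64`, `c5 = 24` were derived
so that, on the 768-channel SPPF output, the block adds 903,346 parameters
and reproduces the printed model sizes (21.2 M -> 22.1 M, +4.25%, under
the stated 4.3% bound).  Initialization: descriptor convs fan-in uniform
with zero bias, fusion conv small-variance noise with zero bias (the gate
starts near a uniform 0.5), `alpha = 1`.

## Detector graph

Release-6 dialect: 6x6/stride-2 stem (padding 2), backbone stages
Conv+C3 with base repeats (3, 6, 9, 3) scaled by `depth_multiple`
(rounded, minimum 1), base widths (64, ..., 1024) scaled by
`width_multiple` and rounded up to multiples of 8, SPPF with three chained
5x5 max-pools, CSP-PAN neck, and three 1x1 head convolutions emitting
`3*(5+nc)` channels at strides 8/16/32.  Batch-norm (affine, eps 1e-3,
momentum 0.03) follows every convolution except the head.  Head biases are
initialized with the standard objectness/class-frequency prior, which
substantially accelerates early training.

The parameter-budget checks use the standard 80-class head — that is the
configuration the printed 21.2 M corresponds to; the MRI task itself uses
`num_classes = 3`.  `before_sppf` splices ESA immediately before the SPPF
layer (also 768 channels), giving a controlled ablation of "early"
placement.

Anchors default to the stock 640-scale set; they are priors in pixels at
the configured input size.  `fit_anchors` provides the standard
re-estimation from a dataset's label extents (k-means on letterboxed
box sizes).  On the desk-scale phantom benchmark the stock set used at
96-pixel input gave the best results — small lesions then concentrate on
the fine stride-8 grid — so the benchmark keeps the stock set.

## Loss and assignment

CIoU uses epsilon 1e-7 in denominators; its aspect-ratio coefficient
`alpha_v` is treated as a constant at the current point (standard
practice).  Assignment is the stock recipe: anchor-ratio test with
threshold 4.0 plus the two nearest neighbor cells (offset 0.5).  Loss
weights default to `lambda_cls = 0.5`, `lambda_obj = 1.0`,
`lambda_loc = 0.05` (the published text names the terms but not the
weights; these are the stock values, exposed in config).  Objectness
targets are the detached, clamped CIoU of the matched prediction;
per-scale objectness balance (4.0, 1.0, 0.4).  Label smoothing 0.1 applies
to classification targets only.

## Data pipeline

Preprocessing is per-image min-max intensity normalization (constant
images map to 0.5) followed by aspect-preserving letterboxing with grey
(114/255) padding.  Augmentations: horizontal flip (p=0.5), rotation
(±10°, boxes replaced by the axis-aligned hull of their rotated corners),
HSV jitter (±0.015 on all three channels — the literal reading of the
published gain), 2x2 mosaic (p=0.5) built on a double-size canvas around
a center in the [0.25, 0.75] band and rescaled, and mixup
(Beta(0.2, 0.2) blend, label union) applied after mosaic with p=0.1 (the
mixup probability is unpublished; 0.1 is this package's choice).
Degenerate boxes after geometric transforms are dropped when the clipped
area falls below 10% of the original or a side falls below 2 px.
Augmentation applies to the training split only.

Splits are stratified by class with largest-remainder rounding (so the
1,426/708/930 corpus yields 1,141/566/744 training images at 80%), and the
five-fold splitter keeps per-class fold sizes within one image.

## Evaluation protocol

AP is the exact area under the monotone precision envelope over all
distinct recall points (not 11/101-point sampling); mAP@0.5:0.95 averages
ten IoU thresholds.  NMS is class-wise greedy (conf 0.25, IoU 0.45 at
deployment).  Aggregate precision/recall are reported at the max-F1 point
of the PR curve, since the published operating rule is not stated.

One deliberate deviation from a literal reading: mAP is computed from
detections above a near-zero confidence floor (0.001), not above the 0.25
deployment threshold.  A PR curve truncated at 0.25 collapses recall for
any imperfectly calibrated model and makes mAP meaningless; standard
detection tooling evaluates at ~0.001 and this package follows that.  The
0.25 threshold still governs `predict` and the confusion matrix.

## Phantom corpus

The generator emulates the *structure* of the study corpus — 3,064
single-lesion 512x512 slices (1,426/708/930 across glioma, meningioma,
pituitary; 233 round-robin synthetic subject ids) — with an invented
appearance model: elliptical bright "skull" ring, multi-octave value-noise
brain texture (intensities ~0.3–0.6), near-black exterior; glioma as a
large (10–20% of the canvas side) irregular low-contrast (+0.08–0.15)
feathered blob, meningioma as a medium (6–12%) rounded blob with a bright
rim, pituitary as a small (3–8%) bright (+0.35–0.50) compact blob near the
slice center.  Masks are generated first and boxes derived from them, so
labels are correct by construction.  It is **not** a physical MRI
simulation (no k-space, bias fields, partial voluming, or anatomy);
passing tests demonstrate that the pipeline's mechanics work and that the
detector can learn a separable three-class localization task, not that the
published accuracy transfers to clinical data.

## Training orchestration

AdamW with decoupled weight decay applied to convolution weights only;
epoch-indexed cosine annealing from `eta_0 = 0.001` over `E` epochs,
preceded by a 3-epoch linear warmup (disable with `warmup_epochs=0` to
recover the pure schedule; the published momentum 0.937 belongs to an SGD
recipe and is not used with AdamW).  Gradient accumulation defaults to
`max(1, 64/batch)`.  The best checkpoint is the highest validation
mAP@0.5; early stopping after 30 stale epochs.  One seed drives weight
init, data order and augmentation, so runs are bit-reproducible.

## Desk-scale benchmark sizes

The end-to-end effectiveness check trains the width-0.25 / depth-0.33
variant (the standard pairing at that width) on the 120/30-image phantom
benchmark (160 px canvas) at 96 px input for 30 epochs over 3 seeds, with
batch 4, no accumulation, `lr0 = 3e-3`, mosaic/mixup off and rotation
limited to ±5° — at ~450 optimizer steps the heavy collage augmentations
only slow convergence.  These sizes are the package's own desk-scale
choices; the check is directional (ESA not worse than baseline, both
above 0.5 mAP@0.5) and does not claim the full-scale improvement.

## Known limitations

- The phantom's appearance model is synthetic and far easier than clinical
  MRI; absolute metric values on it say nothing about patient data.
- The engine is single-threaded numpy: fine for the reduced-width
  configurations used here, not for full-scale 640 px training.
- COCO-pretrained transfer learning is out of scope (a fresh-weights
  `load_state_dict` hook exists, but no weights ship).
- `amp` is accepted and recorded as a flag only; computation is float32.
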