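# Methods

## Problem and model

Colonoscopy frames show polyps whose size, shape and appearance vary widely,
under difficult optics (specular highlights, vignetting, blur, overexposure).
The package segments the polyp region per frame with a fully convolutional
network whose design revolves around matching the receptive field to the
polyp size distribution.

The network is a residual bottleneck backbone (depth 50 by default;
101/152 available) partitioned into stages Res1–Res5, with four parallel
classification paths tapping the outputs of Res2–Res5. Each path applies a
3×3 convolution dilated at rate 16/8/4/2 (finest to coarsest path), ReLU,
dropout, and a 1×1 per-pixel two-class classifier; path scores are
upsampled to the input size with fixed bilinear interpolation and summed.
The dilated kernel at rate r covers a span of (k−1)·r+1 pixels of its
feature map — 33/17/9/5 for the default rates — without adding parameters.
Per-pixel softmax over the fused scores gives the polyp probability map.
Disabling dilation (`use_dilation=False`) leaves an otherwise identical
plain-convolution network for ablation comparisons.

### Spatial-size convention

The stated stage output sizes for a 250×287 input are 62×72, 31×36, 16×18
and 8×9, and the standard 224×224 input must give 56/28/14/7. Both sets are
reproduced exactly by: a 7×7 stride-2 pad-3 stem convolution, a 2×2
stride-2 floor max pool, and ceil(n/2) stride-2 bottleneck downsampling in
Res3–Res5. (The more common 3×3/2 pad-1 stem pool would give 63 rows at
input height 250 and is therefore not used.) Stage layer counts 9/12/18/9
count the bottleneck convolutions only; 1×1 projection shortcuts are
excluded, which is the only convention consistent with those totals.

### Receptive-field analysis

With same-padding, a dilated tap can fall outside the feature map; the
number of "valid weights" per output position is computed in closed form
per axis and verified against exhaustive enumeration in the tests. The
`coverage_fraction` statistic — the fraction of polyps whose extent divided
by the path stride fits the kernel span — is the design rule used to pick
the coarsest path's rate.

## Network engine

No deep-learning framework is used: `polypseg.nn` is a compact NumPy CNN
engine with explicit backward passes (im2col convolution backed by BLAS
matrix products, batch normalization with running statistics, 2×2 max
pooling, inverted dropout, fixed bilinear upsampling expressed as a pair of
1-D interpolation matrices, per-pixel softmax cross-entropy, Adam). All
backward passes are finite-difference checked in `tests/test_nn.py`.
Computation is float32; gradient checks run the same code in float64.

Initialization: He-normal for backbone convolutions, Xavier-uniform for the
classification paths, bilinear (fixed) upsampling. A pretrained-weight hook
(`ArchitectureSpec.pretrained_init`) loads a checkpoint at construction if
provided; nothing requires one.

## Training

Per-pixel two-class cross-entropy on the fused score map (class weighting
deliberately omitted by default), Adam, and the step schedule
`lr(e) = lr0 · γ^(e // d)` with defaults lr0 = 1e-4, γ = 0.1, d = 10 over
30 epochs. Inputs are standardized per channel with statistics of the
training corpus, stored on the network and in checkpoints so inference
reuses them. Batch size defaults to 8; all randomness (shuffling, dropout)
derives from the training seed, making loss traces bit-reproducible.

Cross-validation is grouped by video sequence: whole sequences are
assigned to folds largest-first onto the lightest fold after a seeded
shuffle, so frame counts balance as evenly as sequence sizes allow and no
sequence ever straddles the train/validation split. The training side of
each fold is augmented; the validation side never is.

## Augmentation

Every frame is first rescaled isotropically so both axes cover the
250×287 working size and randomly cropped (translation augmentation), then
an independently sampled composition of the enabled transforms is applied
in the fixed order rotation → scale → TPS → color jitter (the composition
order is a package choice; the transforms are defined independently so
any subset can be enabled for ablations). Geometric transforms warp the
image bilinearly with reflect borders and the mask with nearest-neighbour
and zero borders — reflecting tissue texture is harmless for images, but
masks must not invent polyp pixels at borders.

* Rotation: uniform 0–360°.
* Scale: uniform 0.8–1.2 about the center, frame size fixed.
* Thin-plate spline: a 10×10 control grid, each point displaced by a
  uniform vector with sup-norm ≤ 4 px; the TPS interpolant of the displaced
  grid warps both planes identically.
* HSV jitter: the model records each training image's mean hue, saturation
  and value; a sampled shift is one image's deviation from the corpus grand
  mean, applied with hue wrap-around and S/V clipping. Shifts therefore
  never exceed the spread observed in the corpus, and an all-identical
  corpus yields zero jitter.

`augment_subset` returns an exact requested count with every original
represented at least once, retaining sequence ids so grouping survives
augmentation.

## Inference and post-processing

Rotation test-time augmentation rotates the input in 15° steps (24 views),
predicts each view, inverse-rotates the outputs and averages. The default
aggregation binarizes each view at 0.5 before averaging (`binary_mean`);
`probability_mean` averages raw probabilities instead. Non-square frames
are reflect-padded to the enclosing square before rotation; each output
pixel is normalized by the number of views whose un-padded region covers
it. Rotations by multiples of 90° on square frames use exact quarter-turn
array rotation, which makes the rotation-equivariance contract testable to
the bit. A single-view TTA (angle step 360°) short-circuits to the plain
forward pass.

Binarization: threshold (default 0.5) → morphological opening with a disc
(default radius 2 px; an optional `reference_size` scales the radius
proportionally on other resolutions) → hole filling. The operation is
idempotent.

## Metrics

Counts TP/FP/FN/TN are exact pixel tallies. Conventions: when both masks
are empty, overlap measures are 1; when exactly one is empty, 0 — raw
counts are always recorded so other conventions can be recomputed.
Hausdorff distance uses boundary pixels (foreground 4-adjacent to
background), Euclidean, and is infinite when a boundary is empty; infinite
frames are excluded from means with their count reported. Circularity is
4πA/P² with the perimeter taken from the traced subpixel iso-contour
resampled every 5 vertices — the raw staircase contour overestimates smooth
boundaries by ~5% (a rasterized disc would score ≈ 0.89 instead of ≈ 1);
resampling removes that bias while a 100-px square still scores within 1%
of π/4. Stratification cut points are the 25th/75th percentiles (linear
interpolation) of the training distribution; polyp "size" is area in
pixels, recorded per frame so a linear-extent alternative is recomputable.

## Phantom generator

Phantoms exist to exercise the pipeline, not to imitate colonoscopy
photometry. Each sequence draws one polyp identity — radius log-uniform in
18–60 px (log-uniform keeps the quartile strata non-empty), eccentricity
0–0.6, boundary roughness 0–0.5 as a 4-harmonic polar perturbation, and a
pink/red color pair — and renders ~20 frames of it under jittered position,
gain, noise, vignetting and fresh specular highlights, emulating correlated
frames selected from one video. The blob support is analytic and
star-convex, so the mask is exact and single-component by construction.
Defaults (15 sequences × 20 frames, 250×287, noise σ = 4, vignette 0.35,
0–4 highlights) mirror the structure of a standard-definition polyp
training corpus.

What phantoms do **not** model: real mucosa texture, depth/occlusion,
instruments, luminal darkness, motion blur, multiple polyps. A passing
pipeline-recovery test shows the implementation is correct and trainable,
not that the architecture reaches any particular accuracy on clinical data.

## Desk-scale problem sizes

The test suite trains at reduced scale as its own experimental design: a
single-phantom 200-iteration memorization run at 128×128 (expected
post-processed Dice > 0.95), and a 2-fold, 2-epoch cross-validation on 60
phantoms at full 250×287 resolution with rotation-only augmentation,
learning rate 1e-3, batch 3 (expected mean validation Dice > 0.5, far
above the empty-prediction baseline of 0). The higher learning rate versus
the 30-epoch default is deliberate: with two epochs on simple phantoms the
schedule never reaches its first decay step, and 1e-3 is the standard
small-corpus Adam choice.

## Known limitations

* CPU-only NumPy execution: roughly 0.7 s forward / 1.6 s forward+backward
  per 250×287 frame per core — fine for desk-scale studies, not for
  clinical-corpus training.
* Batch normalization statistics are updated with momentum 0.1; very short
  runs leave running statistics partially calibrated (mitigated at desk
  scale by the higher learning rate and simple phantoms).
* The dilated-path width (64 channels) is a capacity/runtime compromise and
  is configurable; no claim is made that it is optimal.
* Offline augmentation (a fixed augmented corpus per fold) is the default;
  per-epoch resampling is not implemented.
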