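# Methods

This note documents the models, conventions and parameter choices the
package commits to, including the places where the underlying study
left the design open and a choice had to be made.

## Study structure

The analysis treats a whole-slide image (WSI) as carrying three aligned
rasters: a tissue image, a label mask (0 background, 1 healthy tissue,
2 annotated tumor, 3 hard negative), and — after inference — a
tumor-probability heatmap. Slides come from five sources: two public
multicenter sentinel-node sets (CAMELYON16: 399 slides, 239/160
negative/positive, 20 positives only partially annotated; CAMELYON17:
344 used slides after excluding 16 ITC-only slides from its 50
annotated positives), two local sets (LocalSentinel 107/54,
LocalAxillary 24+9/24 where the +9 are extra-nodal enrichment slides),
and a negative-only axillary set of 259 slides used solely to measure
false-positive burden. Slides whose only finding is isolated tumor
cells (≤ 0.2 mm) are node-negative under TNM and are excluded before
any splitting. Public splits are fixed; the local sets are split by
stratified random sampling with exact per-class counts (58/30, 15/7,
34/17 for LocalSentinel; 11+6/13, 3+3/4, 10/7 for LocalAxillary, the
enrichment slides going 6 to train and 3 to validation). The split is
exact-count sampling, not per-slide Bernoulli: the published cell
counts are not fractions of the totals, so only exact sampling
reproduces them.

## Synthetic cohorts

The generator emulates the statistical structure the analysis consumes,
not histology. A slide is a low-entropy two-level texture (a wavy
central tissue ellipse on background); lesions are random ellipses
whose major axis is the controlled "diameter" — diameter is the only
geometric property any downstream rule consumes. Default diameter
ranges are U(0.3, 2.0) mm for micro, U(2.5, 8.0) mm for macro and
U(0.05, 0.2) mm for ITC: the classes deliberately avoid the 0.2 mm and
2 mm boundaries so that raster-measurement error of a planted diameter
can never flip its class. Lesion sets that cannot be placed without
overlap are redrawn wholesale (rejection sampling of the layout);
a lesion larger than the slide raises a sizing error.

Heatmap scores are clipped normals: in-lesion N(0.90, 0.05) on
[0.5, 1], background N(0.08, 0.04) on [0, 0.3], confounder blobs
N(0.70, 0.15) on [0.5, 1]. The study does not characterize the score
distribution of real model outputs, so these are stand-ins, exposed in
the spec objects; the degenerate "perfect" preset (lesions exactly 1,
background 0) makes planted-truth recovery exact. Confounder blobs
arrive at a Poisson rate per slide (presets 35 and 1.3 emulate the
observed per-slide false-positive burden before and after local
retraining) and are rejection-sampled to overlap neither lesions nor
each other, with a one-pixel margin; consequently every blob is its own
detection and the cohort's FROC/AUC are computable by enumeration from
the recorded truth. This is the one deliberate departure from realism —
real false positives can touch real lesions — and it is what makes the
planted-truth tests exact rather than approximate.

Geometry: a slide's nominal resolution is 0.5 µm/px (this is what patch
arithmetic uses: a 279 px patch spans 139.5 µm), but rasters are
generated at a configurable working spacing, default 16 µm/px, so a
20 mm slide is a 1250² array rather than a 40,000² one. All coordinates
are micrometers, origin top-left, x right, y down; heatmaps carry their
grid spacing and offset explicitly.

Passing tests on these cohorts therefore shows that the *pipeline* is
correct (components, filters, matching, statistics), not that any
detector performs well on real tissue: there is no stain variation, no
scanner artifact, no hard morphology.

## Network

The classifier is a DenseNet variant with valid padding: three dense
blocks, each alternating four 1×1 convolutions (64 channels) and three
3×3 convolutions (32 channels), starting and ending on a 1×1. Each 1×1
layer receives the concatenation of the block input and all preceding
3×3 outputs, center-cropped to the current spatial size — under valid
padding every 3×3 shrinks the map by 2 px, so crops are always
symmetric; this is the most direct reading of the published
skip-connection description, and the package verifies it only against
its own shape oracle. Blocks 1–2 are followed by a transition (1×1
convolution + 2×2 average pooling, stride 2, odd trailing row/column
dropped — the common valid-pooling convention; the source is silent),
block 3 by a single 3×3 convolution onto two class logits. Batch
normalization and ReLU follow every convolution except the last, which
gets a soft-max. Weights are He-initialized; biases exist only on the
final convolution.

With the default configuration the minimum field of view is 54 px and
the output stride 4, so a 279×279 patch yields a 57×57 output map;
supervision (and patch labels) attach to the center position, matching
the center-pixel labelling of the patch regime. Valid padding implies
exact agreement between patchwise and fully convolutional inference;
`predict_slide` exploits this to tile arbitrarily (tile starts are
multiples of the output stride, so pooling alignment is preserved and
tiling is bit-invisible). Heatmap pixels sit at the center of their
receptive field: spacing = input spacing × stride, offset = (fov−1)/2.
Non-tissue output positions are zeroed.

The implementation is plain numpy in NHWC layout: convolutions as k²
shifted channel-matmuls (BLAS), explicit backward passes, Adam, and
eval-mode batch norm running statistics for inference. `NetworkConfig`
scales every dimension so the test suite trains one-block, few-channel
instances in seconds; the defaults are the full-scale architecture.

## Training

Per epoch the sampler draws a fresh patch set (full-scale default
262,144 patches for training and validation individually; the test
default is a few thousand) with a Bernoulli 20/80 tumor/healthy mix;
the realized mix is binomial by construction. A patch's label is its
center pixel's mask code. Local upweighting multiplies every local
slide-pixel's sampling weight by a configured factor; hard negative
mining multiplies code-3 pixels' weight within the healthy class.
Validation patches are resampled per epoch from a fixed per-epoch seed
sequence so validation accuracy is comparable across epochs.

Augmentations apply in a fixed order — horizontal flip, quarter-turn
rotation, scaling [0.9, 1.1], hue ±0.1, saturation ±0.25, brightness
±0.25, contrast ±0.25, Gaussian noise sd ≤ 0.05, Gaussian blur sd ≤ 1 —
with parameters drawn uniformly. Hue/saturation are fractional offsets
in HSV; brightness is additive and contrast multiplicative in RGB (the
published ranges are unitless fractions). Scaling resamples and then
center-crops or edge-pads back, so patch shape and label never change;
output is clipped to [0, 1]; every parameter at its identity value is a
bit-exact no-op, and each draw is logged.

Optimization is Adam (framework-default β's, logged) at LR 10⁻⁴ with
categorical cross-entropy and L2 weight 10⁻⁴. "No improvement" means
not strictly greater than the best validation accuracy so far (the
conservative reading of the published schedule): after 4 consecutive
stale epochs the LR drops by 10 (the drop counter then resets), after
20 training stops, and 200 epochs is the cap; the best-validation
checkpoint is returned. The schedule is a pure function of the
validation-accuracy sequence and is unit-tested as such. Validation
accuracy is patch accuracy (whether the original study validated on
patches or slides is unstated).

The three retraining strategies compose freely: `scratch_pooled`
re-initializes and trains on all sources, `finetune_local` loads the
base checkpoint and trains on local sources only; sampling is uniform
or locally upweighted; hard negative mining toggles the code-3 weight.
The full-scale strategy grid is runnable only at toy scale here.

## Hard negative mining

From an initial model's heatmap, regions scoring ≥ 0.5 (the boundary
pixel at exactly 0.5 is retained) that are strictly larger than 0.2 mm
and share no pixel with any ground-truth lesion are added to the label
mask as code 3, only overwriting code 1. "Overlap" is pixel overlap
(the source does not say whether it meant pixels or bounding boxes).
Note the deliberate boundary asymmetry, both honored literally: mining
requires *strictly more* than 0.2 mm, while detection filtering keeps
*exactly* 0.2 mm (it excludes only "less than"); a region of exactly
0.2 mm is therefore retained as a detection yet yields slide label
negative and is never mined. One mining round is supported — the study
describes a single round.

## Detection and slide labelling

Components of {score ≥ 0.5} under 8-connectivity (8 rather than 4 so
diagonal blobs do not split; fixed project-wide and shared with
mining). The 0.5 operating point is stated only for mining in the
source; reusing it for detection keeps one project-wide threshold and
it is a CLI flag. A region's diameter is the major axis of its
moment-matched ellipse in millimeters — stable on raster regions and
consistent with the pathologist's long-axis measurement. The slide
score is the maximum retained score (0 if none); the automatic TNM
label comes from the largest retained diameter (> 2 mm macro,
> 0.2–≤ 2 mm micro, else negative). Detections export as ASAP-dialect
XML (for PACS review) and as (slide_id, x, y, score) CSV.

## Metrics and inference

AUC is the Mann–Whitney statistic over positive/negative slide-score
pairs with ties counting ½, computed from midranks. FROC sweeps a
threshold over all distinct detection-point scores: a lesion is hit if
at least one retained point lies inside it (points inside lesions are
matched on the raster grid, with the same rasterization used to plant
them, so boundary pixels cannot leak); false positives are points
outside all lesions, counted on metastasis-free slides only. The FROC
score averages sensitivity at FP rates ¼, ½, 1, 2, 4, 8 per slide;
sensitivity "at" a rate is the maximum over thresholds whose FP rate
does not exceed the target (step-function reading, no interpolation),
and rates beyond the curve's maximum reuse the terminal sensitivity so
a model with few false positives is not penalized at generous
allowances.

Bootstrap CIs are 95% percentile intervals over 10,000 resamples of
slides (slides, not lesions, are the sampling units); resamples on
which a statistic is undefined are redrawn. Permutation tests are
two-sided on the absolute difference with the add-one correction,
10,000 permutations; both unpaired (shuffle slide-to-group assignment)
and paired (swap the two models' per-slide results with probability ½)
modes exist because the study does not state which it used per
comparison. All resampling is seed-reproducible.

Calibration is checked by simulation at reduced resampling counts (500
permutations / 500 bootstrap resamples, 200 replications): the null
rejection rate at α = 0.05 and the coverage of the closed-form AUC
Φ(Δµ/σ√2) of a Gaussian two-group score model (50/50 slides,
true AUC ≈ 0.80) must each lie within three binomial standard errors of
nominal.

## Problem sizes

Tests and the acceptance script use desk-scale instances chosen once:
planted-truth cohorts of 100 slides (8 mm slides at 16 µm/px),
false-positive presets measured over 60–100 negative 10 mm slides,
network contracts on scaled-down configurations (the 2,000² raster
tiling check uses a two-block, few-channel instance), training sanity
on ~50 patches at a 9 px patch size, and 200-replication calibration
loops. Full-scale defaults (279 px patches, 262,144 patches/epoch,
10,000 resamples) remain the documented configuration values.

## Known limitations

- No histology realism: texture, stain and scanner variation, ILC
  morphology, partially annotated slides' delineation logic and the
  qualitative pathologist review are out of scope.
- The real-data headline metrics require the WSI archives and
  GPU-scale training; nothing here claims detector performance on
  tissue.
- The dense-block skip wiring follows one self-consistent reading of
  the published description; the original implementation may differ in
  cropping details (it is verified against this package's own
  shape/equivariance oracles, not against original weights).
- The numpy network is single-threaded BLAS-bound; it is meant for
  correctness and small-scale experiments, not throughput.
- Confounder blobs never touch lesions or each other — an
  intentional simplification that buys exact planted-truth oracles.
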