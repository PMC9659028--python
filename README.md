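# lymphmet

A reusable, testable re-implementation of a breast-cancer lymph-node
metastasis detection study: how well does a patch-based convolutional
detector trained on multicenter sentinel-node slides generalize to a
new laboratory and to a changed surgical indication (axillary
dissection), and how should it be retrained when it does not?

The package is aimed at computational-pathology researchers who want
the study's machinery — cohort bookkeeping, the detector architecture,
the retraining strategies, the heatmap post-processing, and the
evaluation statistics — as importable, unit-tested components, with a
synthetic whole-slide generator standing in for the clinical archives
(AIDA BRLN, CAMELYON16/17), which are not required.

## What is implemented

**Cohorts** (`lymphmet.cohort`). Slide manifests built from published
dataset compositions; exclusion of slides whose only finding is
isolated tumor cells (ITC, ≤ 0.2 mm — node-negative under TNM);
stratified random splits with exact per-class counts next to the fixed
public splits. Rebuilding the full study manifest reproduces every
published marginal count (961 slides, 344 from CAMELYON17 after ITC
exclusion, a combined local test set of 68 slides).

**Synthetic slides** (`lymphmet.synthetic`). Single-level tissue
rasters with planted elliptical lesions of controlled diameter (micro
0.2–2 mm, macro > 2 mm, ITC ≤ 0.2 mm), label masks (0 background,
1 healthy, 2 tumor, 3 hard negative), and model-like tumor-probability
heatmaps in which lesions score high and benign-confounder blobs
produce false positives at a Poisson rate. Confounders are
rejection-sampled to overlap nothing, so detection and FROC behaviour
are analytically known from the recorded planted truth.

**Network** (`lymphmet.network`). A modified DenseNet with *valid*
padding: 3 dense blocks of alternating 1×1 (64-channel) and 3×3
(32-channel) convolutions with concatenating skip connections,
transition blocks (1×1 conv + 2×2 average pooling), a final 3×3
convolution, batch norm + ReLU everywhere except the soft-max output,
He initialization. Valid padding makes patchwise and fully
convolutional inference agree exactly, so whole-slide heatmaps can be
computed in tiles with no border effects (`predict_slide`). The
forward/backward passes are plain numpy (BLAS matmuls); the
architecture is scalable so tests train tiny instances.

**Training** (`lymphmet.training`, `lymphmet.augment`). The 20/80
tumor/healthy patch sampler with per-epoch reseeding; the augmentation
stack (flip, quarter rotations, scale 0.9–1.1, hue ±0.1, saturation /
brightness / contrast ±0.25, Gaussian noise ≤ 0.05, blur ≤ 1.0, applied
in that order); Adam with categorical cross-entropy and L2 10⁻⁴; a
plateau schedule (LR ÷10 after 4 stale epochs, early stop after 20, max
200) and best-validation checkpointing; and the three retraining
strategies — scratch on pooled data vs fine-tuning on local data,
uniform vs locally upweighted sampling, and hard negative mining.

**Hard negative mining** (`lymphmet.hnm`). Heatmap regions scoring
≥ 0.5, strictly larger than ITC size, with zero pixel overlap with
ground truth are written into the label mask as code 3; codes 0 and 2
are never touched and the update is idempotent.

**Detection & TNM labelling** (`lymphmet.detection`). 8-connected
heatmap components at threshold 0.5; per-region score (max
probability), detection point (its location) and diameter (major axis
of the moment ellipse, in mm); exclusion of detections < 0.2 mm; slide
score = max retained score; automatic slide label from the largest
retained diameter (macro > 2 mm, micro > 0.2–≤ 2 mm, else negative);
ASAP-dialect XML export for pathologist review.

**Metrics** (`lymphmet.metrics`). Slide-level AUC (Mann–Whitney,
ties ½); lesion-level FROC (sensitivity vs mean false-positive points
per metastasis-free slide) summarized as the mean sensitivity at FP
rates ¼, ½, 1, 2, 4, 8; 95% bootstrap percentile CIs (10,000 resamples
of slides); paired and unpaired permutation tests (10,000 permutations,
two-sided, add-one corrected).

## Worked example

Planted-truth recovery end to end (`analysis/03_planted_truth_eval.py`):

```
Perfect planted cohort: AUC=1.000 FROC=1.000 (both must be exactly 1.0)
With confounders (rate 2/slide): AUC=0.540 (95% CI 0.509-0.583), FROC=0.333 (95% CI 0.333-0.500)
Enumeration oracle FROC=0.333 (pipeline-oracle gap 0.00e+00)
FP preset 35/slide  -> mean retained detections 33.17
FP preset 1.3/slide -> mean retained detections 1.32
```

On 100 synthetic slides whose lesions score exactly 1.0 and whose
heatmaps carry no confounders, the full pipeline (heatmap → connected
components → ITC-size filter → point-in-lesion matching → metrics)
recovers AUC = 1 and FROC = 1 exactly. Adding two confounder blobs per
slide with scores overlapping the lesion-score distribution degrades
FROC to 0.333, and the pipeline's value agrees to machine precision
with an enumeration computed purely from the generator's planted truth
— the detection stack neither loses nor invents regions. The two
false-positive presets emulate the per-slide FP burden of a detector
before (~35/slide) and after (~1.3/slide) retraining on local axillary
data; the printed means are Poisson sampling means of those rates.

The numbered scripts under `analysis/` run the full sequence: manifest
construction, cohort simulation, planted-truth evaluation, toy-scale
strategy training, hard negative mining, and statistical calibration,
each writing its tables to `results/`. The same stages are scriptable
through the CLI (`lymphmet simulate|split|train|predict|mine|evaluate|compare`,
each taking a YAML config and a seed).

## Scope notes

The study's headline real-data metrics (e.g. base-model CAMELYON16
AUC 0.969 / FROC 0.838) require the full WSI archives and GPU-scale
training and are out of scope here; the package reproduces everything
that is determined by the published tables and by the methods
themselves, at desk scale. See `docs/methods.md` for the model
assumptions, parameter choices, and limitations.
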