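"""Slide-level AUC, lesion-level FROC, bootstrap CIs, permutation tests.

The slide score is the maximum retained detection probability on the
slide (0 if nothing is retained), and slide-level AUC is the
Mann–Whitney statistic of positive-vs-negative slide scores (ties count
half).  For FROC, each retained detection contributes one point — the
location of its maximum — which is a true positive if it falls inside a
ground-truth lesion and a false positive otherwise; a lesion is hit if
at least one point lies within it (multiple points count once).  The
FROC curve relates lesion sensitivity to the average number of
false-positive points per metastasis-free slide, and the FROC score is
the mean sensitivity at six predefined false-positive rates: 1/4, 1/2,
1, 2, 4 and 8 per slide.

Sensitivity "at" a rate is read off the curve as the maximum
sensitivity over thresholds whose false-positive rate does not exceed
the target (step-function reading, no interpolation); beyond the
curve's largest attainable rate the terminal sensitivity carries over,
so a model with few false positives is not penalized at generous rates.

Confidence intervals are 95% percentile intervals over 10,000 bootstrap
resamples of slides; significance uses permutation tests (10,000
permutations, two-sided on the absolute difference, add-one corrected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from lymphmet.annotations import AnnotationSet
from lymphmet.detection import DetectionRegion, SlidePrediction
from lymphmet.heatmap import Heatmap

PREDEFINED_FP_RATES: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

DEFAULT_N_BOOTSTRAP = 10_000
DEFAULT_N_PERMUTATIONS = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class SlideEval:
    """Per-slide reduction sufficient for AUC and FROC.

    ``lesion_scores`` has one entry per ground-truth lesion: the highest
    score among detection points inside it, or ``None`` if no point hit
    it.  ``fp_scores`` are the scores of detection points outside every
    lesion.  ``slide_score`` is the slide-level max retained score.
    """

    slide_id: str
    is_positive: bool
    slide_score: float = 0.0
    lesion_scores: list[float | None] = field(default_factory=list)
    fp_scores: list[float] = field(default_factory=list)

    @property
    def n_lesions(self) -> int:
        return len(self.lesion_scores)


def match_detections(
    slide_id: str,
    is_positive: bool,
    detections: Sequence[DetectionRegion],
    annotations: AnnotationSet,
    heatmap: Heatmap,
) -> SlideEval:
    """Assign detection points to lesions on the heatmap's pixel grid.

    Lesion membership uses the same rasterization as mask generation, so
    a detection whose maximum sits on a lesion's boundary pixel is
    counted inside it.
    """
    lesion_label = annotations.rasterize(
        heatmap.values.shape, heatmap.spacing_um, heatmap.offset_um)
    lesion_scores: list[float | None] = [None] * len(annotations)
    fp_scores: list[float] = []
    for det in detections:
        owner = int(lesion_label[det.point_px])
        if owner > 0:
            prev = lesion_scores[owner - 1]
            if prev is None or det.score > prev:
                lesion_scores[owner - 1] = det.score
        else:
            fp_scores.append(det.score)
    return SlideEval(
        slide_id=slide_id,
        is_positive=is_positive,
        slide_score=max((d.score for d in detections), default=0.0),
        lesion_scores=lesion_scores,
        fp_scores=fp_scores,
    )


# --------------------------------------------------------------------------
# AUC
# --------------------------------------------------------------------------


def slide_auc(scores: Sequence[float], positive: Sequence[bool]) -> float:
    """Mann–Whitney AUC over all positive/negative slide pairs.

    Computed from midranks (ties count half), so it equals the
    trapezoidal ROC area.
    """
    positive = np.asarray(positive, dtype=bool)
    scores = np.asarray(scores, dtype=np.float64)
    if positive.all() or (~positive).all():
        raise ValueError("AUC needs at least one positive and one negative slide")
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    ranks = rankdata(scores)  # average ranks on ties
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_statistic(slides: Sequence[SlideEval]) -> float:
    return slide_auc([s.slide_score for s in slides],
                     [s.is_positive for s in slides])


# --------------------------------------------------------------------------
# FROC
# --------------------------------------------------------------------------


@dataclass
class FROCCurve:
    thresholds: np.ndarray  # descending
    fp_rates: np.ndarray  # avg FP points per metastasis-free slide
    sensitivities: np.ndarray  # hit lesions / total lesions
    n_lesions: int
    n_negative_slides: int

    def sensitivity_at(self, fp_rate: float) -> float:
        """Max sensitivity over curve points with FP rate <= target."""
        ok = self.fp_rates <= fp_rate + 1e-12
        if not ok.any():
            return 0.0
        return float(self.sensitivities[ok].max())


def froc(slides: Sequence[SlideEval]) -> FROCCurve:
    """FROC curve by sweeping a threshold over all distinct scores."""
    n_lesions = sum(s.n_lesions for s in slides)
    negatives = [s for s in slides if not s.is_positive]
    if n_lesions == 0:
        raise ValueError("FROC needs at least one ground-truth lesion")
    if not negatives:
        raise ValueError("FROC needs at least one metastasis-free slide")
    lesion_scores = np.array(
        [sc for s in slides for sc in s.lesion_scores if sc is not None],
        dtype=np.float64,
    )
    neg_fp_scores = np.array(
        [sc for s in negatives for sc in s.fp_scores], dtype=np.float64)
    thresholds = np.unique(np.concatenate([lesion_scores, neg_fp_scores]))[::-1]

    sens = [0.0]
    fp = [0.0]
    ths = [np.inf]
    for th in thresholds:
        sens.append(float((lesion_scores >= th).sum()) / n_lesions)
        fp.append(float((neg_fp_scores >= th).sum()) / len(negatives))
        ths.append(float(th))
    return FROCCurve(
        thresholds=np.array(ths),
        fp_rates=np.array(fp),
        sensitivities=np.array(sens),
        n_lesions=n_lesions,
        n_negative_slides=len(negatives),
    )


def froc_score(curve: FROCCurve,
               fp_rates: Sequence[float] = PREDEFINED_FP_RATES) -> float:
    """Mean sensitivity across the predefined false-positive rates."""
    return float(np.mean([curve.sensitivity_at(r) for r in fp_rates]))


def froc_statistic(slides: Sequence[SlideEval]) -> float:
    return froc_score(froc(slides))


# --------------------------------------------------------------------------
# resampling inference
# --------------------------------------------------------------------------


def bootstrap_ci(
    statistic: Callable[[list], float],
    slides: Sequence,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    level: float = 0.95,
    seed: int = 0,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Percentile CI of a slide-level statistic under resampling.

    Slides (the sampling units) are drawn with replacement; resamples on
    which the statistic is undefined (e.g. single-class) are redrawn.
    """
    if len(slides) < 2:
        raise ValueError("bootstrap needs at least two slides")
    rng = np.random.default_rng(seed)
    slides = list(slides)
    n = len(slides)
    values = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                values[b] = statistic([slides[i] for i in idx])
                break
            except ValueError:
                continue
        else:
            raise ValueError("statistic undefined on all bootstrap resamples")
    alpha = 1.0 - level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def permutation_test(
    group_a: Sequence,
    group_b: Sequence,
    statistic: Callable[[list], float],
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    seed: int = 0,
    paired: bool = False,
    max_redraws: int = 1000,
) -> float:
    """Two-sided permutation p-value for a difference in a statistic.

    Unpaired: slide-to-group assignment is shuffled (group sizes kept).
    Paired: groups are the two models' per-slide results on the same
    slides, and each slide's pair is swapped with probability 1/2.
    The p-value uses the add-one correction.
    """
    a, b = list(group_a), list(group_b)
    if paired and len(a) != len(b):
        raise ValueError("paired test needs equal-length groups")
    observed = abs(statistic(a) - statistic(b))
    rng = np.random.default_rng(seed)
    pooled = a + b
    n_a = len(a)
    count = 0
    for _ in range(n_permutations):
        for attempt in range(max_redraws):
            if paired:
                swap = rng.uniform(size=n_a) < 0.5
                pa = [b[i] if s else a[i] for i, s in enumerate(swap)]
                pb = [a[i] if s else b[i] for i, s in enumerate(swap)]
            else:
                perm = rng.permutation(len(pooled))
                pa = [pooled[i] for i in perm[:n_a]]
                pb = [pooled[i] for i in perm[n_a:]]
            try:
                delta = abs(statistic(pa) - statistic(pb))
                break
            except ValueError:
                continue
        else:
            raise ValueError("statistic undefined on all permutations")
        if delta >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_permutations + 1)


# --------------------------------------------------------------------------
# packaged evaluation result
# --------------------------------------------------------------------------


@dataclass
class EvalResult:
    auc: float
    froc: float
    auc_ci: tuple[float, float]
    froc_ci: tuple[float, float]
    n_slides: int
    n_lesions: int
    n_bootstrap: int
    level: float = 0.95

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate(slides: Sequence[SlideEval],
             n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
             seed: int = 0) -> EvalResult:
    """AUC and FROC with bootstrap confidence intervals."""
    slides = list(slides)
    return EvalResult(
        auc=auc_statistic(slides),
        froc=froc_statistic(slides),
        auc_ci=bootstrap_ci(auc_statistic, slides, n_bootstrap, seed=seed),
        froc_ci=bootstrap_ci(froc_statistic, slides, n_bootstrap,
                             seed=seed + 1),
        n_slides=len(slides),
        n_lesions=sum(s.n_lesions for s in slides),
        n_bootstrap=n_bootstrap,
    )
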