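"""End-to-end glue: simulated slides → detections → slide evaluations.

Two routes produce the per-slide reductions that AUC/FROC consume:

* the pipeline route runs the real post-processing (threshold the
  heatmap, 8-connected components, ITC-size filter, point-in-lesion
  matching on the raster grid);
* the planted-truth route reads the generator's recorded truth (each
  lesion's and confounder blob's realized maximum score) directly.

Because synthetic confounders never touch lesions or each other, the
two routes must agree exactly on well-formed cohorts; the truth route
is the enumeration oracle for planted-truth recovery checks.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from lymphmet.detection import (
    DEFAULT_THRESHOLD,
    ITC_FILTER_MM,
    SlidePrediction,
    extract_detections,
    filter_itc_size,
)
from lymphmet.metrics import SlideEval, match_detections
from lymphmet.synthetic import SlideSim


def pipeline_slide_evals(
    sims: Iterable[SlideSim],
    threshold: float = DEFAULT_THRESHOLD,
    min_diameter_mm: float = ITC_FILTER_MM,
) -> tuple[list[SlideEval], list[SlidePrediction]]:
    """Full post-processing route over simulated slides."""
    evals: list[SlideEval] = []
    predictions: list[SlidePrediction] = []
    for sim in sims:
        detections = filter_itc_size(
            extract_detections(sim.heatmap, threshold), min_diameter_mm)
        predictions.append(
            SlidePrediction(slide_id=sim.record.slide_id, detections=detections))
        evals.append(match_detections(
            sim.record.slide_id,
            sim.record.is_positive,
            detections,
            sim.annotations,
            sim.heatmap,
        ))
    return evals, predictions


def truth_slide_evals(
    sims: Iterable[SlideSim],
    threshold: float = DEFAULT_THRESHOLD,
    min_diameter_mm: float = ITC_FILTER_MM,
) -> list[SlideEval]:
    """Planted-truth route: evaluations enumerated from generator records.

    A planted lesion is its own detection (its in-lesion maximum is the
    component maximum and lies inside it) when its maximum reaches the
    threshold and its planted diameter passes the size filter; each
    confounder blob is one false-positive detection likewise.
    """
    evals: list[SlideEval] = []
    for sim in sims:
        lesion_scores: list[float | None] = []
        retained: list[float] = []
        for lesion, max_score in zip(sim.annotations, sim.truth.lesion_max_scores):
            keep = (max_score >= threshold
                    and lesion.diameter_mm is not None
                    and lesion.diameter_mm >= min_diameter_mm)
            lesion_scores.append(max_score if keep else None)
            if keep:
                retained.append(max_score)
        fp_scores = [
            b.max_score for b in sim.truth.fp_blobs
            if b.max_score >= threshold and b.diameter_mm >= min_diameter_mm
        ]
        retained.extend(fp_scores)
        evals.append(SlideEval(
            slide_id=sim.record.slide_id,
            is_positive=sim.record.is_positive,
            slide_score=max(retained, default=0.0),
            lesion_scores=lesion_scores,
            fp_scores=fp_scores,
        ))
    return evals
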