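"""Hard negative mining: heatmap + ground truth → updated label mask.

An initial model's whole-slide heatmap is thresholded at 0.5; connected
prediction regions larger than ITC size (> 0.2 mm, strict) that do not
touch any ground-truth lesion pixel are "hard negatives" — benign
morphology the model mistakes for tumor.  They are written into the
training label mask as code 3, so the patch sampler can oversample them
during retraining.

Mask codes: 0 background, 1 healthy tissue, 2 ground-truth tumor,
3 hard negative.  Mining never touches codes 0 and 2, and only
overwrites code 1; applying it twice changes nothing.

Boundary conventions, honoured literally and deliberately asymmetric to
the detection module: a pixel scoring exactly 0.5 is retained (>=), and
a region of exactly 0.2 mm is NOT mined ("> 0.2 mm" is strict here,
while the detection filter keeps exactly 0.2 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lymphmet.annotations import AnnotationSet
from lymphmet.detection import DetectionRegion, extract_detections
from lymphmet.heatmap import Heatmap
from lymphmet.synthetic import (
    CODE_BACKGROUND,
    CODE_HARD_NEGATIVE,
    CODE_HEALTHY,
    CODE_TUMOR,
    build_label_mask,
)

DEFAULT_THRESHOLD = 0.5
MIN_DIAMETER_MM = 0.2


@dataclass
class LabelMask:
    """Integer training mask with physical spacing."""

    codes: np.ndarray  # uint8, values in {0, 1, 2, 3}
    spacing_um: float

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if not np.isin(self.codes, [CODE_BACKGROUND, CODE_HEALTHY,
                                    CODE_TUMOR, CODE_HARD_NEGATIVE]).all():
            raise ValueError("mask codes must be in {0, 1, 2, 3}")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")


@dataclass
class MinedRegion:
    """One hard-negative region: component pixels plus detection data."""

    pixels: np.ndarray  # (N, 2) array of (row, col) on the heatmap grid
    detection: DetectionRegion


def mine_hard_negatives(
    heatmap: Heatmap,
    annotations: AnnotationSet,
    threshold: float = DEFAULT_THRESHOLD,
    min_diameter_mm: float = MIN_DIAMETER_MM,
    detections: list[DetectionRegion] | None = None,
) -> list[MinedRegion]:
    """Connected regions of {score >= threshold}, strictly larger than
    ITC size, with zero pixel overlap with any ground-truth lesion.

    ``detections`` may inject precomputed regions (sharing the
    heatmap's grid); by default they are extracted from the heatmap.
    """
    from skimage import measure

    values = heatmap.values
    labels = measure.label(values >= threshold, connectivity=2)
    lesion_label = annotations.rasterize(
        values.shape, heatmap.spacing_um, heatmap.offset_um)
    if detections is None:
        detections = extract_detections(heatmap, threshold)
    mined: list[MinedRegion] = []
    for det in detections:
        comp_id = labels[det.point_px]
        coords = np.argwhere(labels == comp_id)
        if det.diameter_mm <= min_diameter_mm:  # strict: exactly 0.2 mm is out
            continue
        if (lesion_label[coords[:, 0], coords[:, 1]] > 0).any():
            continue  # any overlap with ground truth excludes the region
        mined.append(MinedRegion(pixels=coords, detection=det))
    return mined


def update_label_mask(mask: LabelMask, regions: list[MinedRegion]) -> LabelMask:
    """Set mined pixels to code 3 where the prior code is healthy tissue.

    Codes 0 (background) and 2 (ground-truth tumor) are never
    overwritten; the operation is idempotent.
    """
    codes = mask.codes.copy()
    for region in regions:
        rows, cols = region.pixels[:, 0], region.pixels[:, 1]
        if (rows < 0).any() or (cols < 0).any() or \
                (rows >= codes.shape[0]).any() or (cols >= codes.shape[1]).any():
            raise ValueError("mined region outside mask bounds")
        sel = codes[rows, cols] == CODE_HEALTHY
        codes[rows[sel], cols[sel]] = CODE_HARD_NEGATIVE
    return LabelMask(codes=codes, spacing_um=mask.spacing_um)


def mine_and_update(
    heatmap: Heatmap,
    annotations: AnnotationSet,
    tissue: np.ndarray,
    spacing_um: float,
    threshold: float = DEFAULT_THRESHOLD,
    min_diameter_mm: float = MIN_DIAMETER_MM,
) -> LabelMask:
    """Full protocol: build the base mask, mine, and update."""
    base = LabelMask(codes=build_label_mask(tissue, annotations, spacing_um),
                     spacing_um=spacing_um)
    regions = mine_hard_negatives(heatmap, annotations, threshold,
                                  min_diameter_mm)
    return update_label_mask(base, regions)
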