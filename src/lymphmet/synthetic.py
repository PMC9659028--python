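"""Synthetic whole-slide cohorts with planted metastases.

Stands in for the clinical slide archives: each synthetic slide is a
single-level tissue raster with polygon ground-truth lesions of
controlled diameter (ITC ≤ 0.2 mm, micro 0.2–2 mm, macro > 2 mm), and a
model-like tumor-probability heatmap in which the planted lesions score
high and benign-confounder blobs produce false-positive detections at a
configurable Poisson rate.  Because confounders are rejection-sampled to
overlap neither lesions nor each other, the detection and FROC behaviour
of a synthetic cohort is analytically known from the planted truth,
which every generator records.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from lymphmet.annotations import AnnotationSet, Lesion
from lymphmet.cohort import Manifest, SlideRecord
from lymphmet.heatmap import Heatmap, write_mask_tiff
from lymphmet.tnm import gt_label_from_diameters

# label-mask codes (shared with hard negative mining)
CODE_BACKGROUND = 0
CODE_HEALTHY = 1
CODE_TUMOR = 2
CODE_HARD_NEGATIVE = 3

#: tissue raster value threshold separating tissue from background
TISSUE_THRESHOLD = 0.3


@dataclass
class ScoreDist:
    """Clipped-normal score distribution on [low, high] ⊆ [0, 1]."""

    mean: float
    sd: float = 0.0
    low: float = 0.0
    high: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.low <= self.high <= 1.0):
            raise ValueError("score bounds must satisfy 0 <= low <= high <= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        if self.sd == 0:
            return np.full(size, np.clip(self.mean, self.low, self.high),
                           dtype=np.float32)
        x = rng.normal(self.mean, self.sd, size=size)
        return np.clip(x, self.low, self.high).astype(np.float32)


@dataclass
class CohortSpec:
    """Composition and geometry of one synthetic dataset.

    ``pixel_spacing_um`` is the slide's nominal level-0 spacing (used
    for physical patch geometry); rasters are generated at the coarser
    ``raster_spacing_um`` so a 20 mm slide stays desk-scale in memory.
    """

    dataset_name: str = "synthetic"
    n_negative: int = 0
    n_positive: int = 0
    lesions_per_positive_slide: tuple[int, int] = (1, 3)
    micro_fraction: float = 0.5  # micro vs macro, per lesion
    itc_fraction: float = 0.0  # positive slide carries only ITC-sized lesions
    confounder_rate: float = 0.0  # expected benign-confounder blobs per slide
    slide_extent_mm: tuple[float, float] = (20.0, 20.0)
    pixel_spacing_um: float = 0.5
    raster_spacing_um: float = 16.0
    micro_diameter_mm: tuple[float, float] = (0.3, 2.0)
    macro_diameter_mm: tuple[float, float] = (2.5, 8.0)
    itc_diameter_mm: tuple[float, float] = (0.05, 0.2)
    procedure: str = "sentinel"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_negative < 0 or self.n_positive < 0:
            raise ValueError("slide counts must be >= 0")
        for p, name in ((self.micro_fraction, "micro_fraction"),
                        (self.itc_fraction, "itc_fraction")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.confounder_rate < 0:
            raise ValueError("confounder_rate must be >= 0")
        if self.pixel_spacing_um <= 0 or self.raster_spacing_um <= 0:
            raise ValueError("pixel spacings must be > 0")
        lo, hi = self.lesions_per_positive_slide
        if not (1 <= lo <= hi):
            raise ValueError("lesions_per_positive_slide must be an ordered range >= 1")

    @property
    def n_slides(self) -> int:
        return self.n_negative + self.n_positive

    def raster_shape(self) -> tuple[int, int]:
        w_mm, h_mm = self.slide_extent_mm
        return (
            int(round(h_mm * 1000.0 / self.raster_spacing_um)),
            int(round(w_mm * 1000.0 / self.raster_spacing_um)),
        )


@dataclass
class HeatmapSpec:
    """Score model for synthetic heatmaps.

    The preset confounder rates of 35 and 1.3 blobs/slide reproduce the
    observed false-positive burden of a sentinel-node detector before
    and after retraining on axillary data.  ``fp_blob_rate=None`` falls
    back to the cohort's ``confounder_rate``.
    """

    in_lesion_score_dist: ScoreDist = field(
        default_factory=lambda: ScoreDist(0.90, 0.05, low=0.5, high=1.0))
    background_score_dist: ScoreDist = field(
        default_factory=lambda: ScoreDist(0.08, 0.04, low=0.0, high=0.3))
    fp_blob_rate: float | None = None
    fp_blob_diameter_range_mm: tuple[float, float] = (0.25, 1.0)
    fp_blob_score_dist: ScoreDist = field(
        default_factory=lambda: ScoreDist(0.70, 0.15, low=0.5, high=1.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fp_blob_rate is not None and self.fp_blob_rate < 0:
            raise ValueError("fp_blob_rate must be >= 0")
        lo, hi = self.fp_blob_diameter_range_mm
        if not (0 < lo <= hi):
            raise ValueError("fp_blob_diameter_range_mm must be positive and ordered")


def perfect_heatmap_spec(fp_blob_rate: float | None = 0.0,
                         seed: int = 0) -> HeatmapSpec:
    """Degenerate score model: lesions score exactly 1, background 0."""
    return HeatmapSpec(
        in_lesion_score_dist=ScoreDist(1.0),
        background_score_dist=ScoreDist(0.0),
        fp_blob_rate=fp_blob_rate,
        seed=seed,
    )


@dataclass
class FPBlob:
    x_um: float
    y_um: float
    diameter_mm: float
    max_score: float


@dataclass
class HeatmapTruth:
    """Planted ground truth of one heatmap, for enumeration oracles."""

    lesion_max_scores: list[float]  # aligned with the AnnotationSet order
    fp_blobs: list[FPBlob]


@dataclass
class SlideSim:
    """One fully simulated slide (in-memory)."""

    record: SlideRecord
    tissue: np.ndarray  # float32 raster, tissue ~0.7, background ~0.05
    annotations: AnnotationSet
    heatmap: Heatmap
    truth: HeatmapTruth

    def label_mask(self) -> np.ndarray:
        return build_label_mask(self.tissue, self.annotations,
                                self.record.spacing_um)


def build_label_mask(tissue: np.ndarray, annotations: AnnotationSet,
                     spacing_um: float) -> np.ndarray:
    """uint8 mask: 0 background, 1 healthy tissue, 2 ground-truth tumor."""
    mask = (np.asarray(tissue) > TISSUE_THRESHOLD).astype(np.uint8)
    lesion_label = annotations.rasterize(mask.shape, spacing_um)
    mask[lesion_label > 0] = CODE_TUMOR
    return mask


# --------------------------------------------------------------------------
# slide generation
# --------------------------------------------------------------------------


def _slide_rng(spec_seed: int, stream: int, slide_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=spec_seed, spawn_key=(stream, slide_index))
    return np.random.default_rng(ss)


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    noise = rng.standard_normal(shape).astype(np.float32)
    noise = ndimage.gaussian_filter(noise, sigma)
    s = noise.std()
    return noise / s if s > 0 else noise


def _ellipse_polygon(cx_um, cy_um, major_um, minor_um, theta, n_vertices=64):
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ex = 0.5 * major_um * np.cos(t)
    ey = 0.5 * minor_um * np.sin(t)
    x = cx_um + ex * np.cos(theta) - ey * np.sin(theta)
    y = cy_um + ex * np.sin(theta) + ey * np.cos(theta)
    return np.stack([x, y], axis=1)


def _draw_lesion_diameter(spec: CohortSpec, rng: np.random.Generator,
                          itc_slide: bool) -> float:
    if itc_slide:
        lo, hi = spec.itc_diameter_mm
    elif rng.uniform() < spec.micro_fraction:
        lo, hi = spec.micro_diameter_mm
    else:
        lo, hi = spec.macro_diameter_mm
    return float(rng.uniform(lo, hi))


def generate_slide(spec: CohortSpec, slide_index: int
                   ) -> tuple[np.ndarray, AnnotationSet, SlideRecord]:
    """Simulate one slide: tissue raster, lesion polygons, slide record.

    Slides ``0 .. n_negative-1`` are negative; the rest are positive and
    carry 1+ planted elliptical lesions whose major axis ("diameter")
    is drawn per the spec.  The ground-truth label applies the TNM rule
    to the largest planted diameter.  Deterministic in
    ``(spec.seed, slide_index)``.
    """
    if not 0 <= slide_index < spec.n_slides:
        raise ValueError(f"slide_index {slide_index} out of range")
    rng = _slide_rng(spec.seed, 0, slide_index)
    shape = spec.raster_shape()
    sp = spec.raster_spacing_um

    # low-entropy tissue footprint: a wavy central ellipse
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    d2 = ((rr - cy) / (0.42 * shape[0])) ** 2 + ((cc - cx) / (0.42 * shape[1])) ** 2
    wave = _smooth_noise(rng, shape, sigma=max(2.0, min(shape) / 25.0))
    footprint = d2 + 0.18 * wave < 1.0
    texture = _smooth_noise(rng, shape, sigma=2.0)
    tissue = np.where(footprint, 0.65 + 0.08 * texture, 0.05 + 0.015 * texture)
    tissue = np.clip(tissue, 0.0, 1.0).astype(np.float32)

    lesions: list[Lesion] = []
    is_positive = slide_index >= spec.n_negative
    if is_positive:
        itc_slide = rng.uniform() < spec.itc_fraction
        n_lesions = int(rng.integers(spec.lesions_per_positive_slide[0],
                                     spec.lesions_per_positive_slide[1] + 1))
        dist_px = ndimage.distance_transform_edt(footprint)
        # whole-layout rejection sampling: if a drawn lesion set cannot be
        # placed without overlaps, redraw the diameters for the slide
        for _layout in range(20):
            lesions = []
            placed: list[tuple[float, float, float]] = []  # (cx, cy, r) um
            layout_ok = True
            for _ in range(n_lesions):
                diameter_mm = _draw_lesion_diameter(spec, rng, itc_slide)
                if diameter_mm >= min(spec.slide_extent_mm):
                    raise ValueError(
                        f"slide extent {spec.slide_extent_mm} mm cannot hold "
                        f"a lesion of diameter {diameter_mm:.2f} mm")
                r_px = 0.5 * diameter_mm * 1000.0 / sp
                candidates = np.argwhere(dist_px >= r_px + 2.0)
                placed_ok = False
                for _attempt in range(200):
                    if len(candidates) == 0:
                        break
                    ci = rng.integers(len(candidates))
                    row, col = candidates[ci]
                    cx_um, cy_um = col * sp, row * sp
                    radius_um = 0.5 * diameter_mm * 1000.0
                    if all(
                        np.hypot(cx_um - px, cy_um - py) > radius_um + pr + 2.0 * sp
                        for px, py, pr in placed
                    ):
                        theta = rng.uniform(0.0, np.pi)
                        minor_mm = diameter_mm * rng.uniform(0.6, 1.0)
                        poly = _ellipse_polygon(
                            cx_um, cy_um, diameter_mm * 1000.0,
                            minor_mm * 1000.0, theta)
                        lesions.append(Lesion(
                            polygon_um=poly,
                            name=f"lesion_{len(lesions)}",
                            diameter_mm=diameter_mm,
                        ))
                        placed.append((cx_um, cy_um, radius_um))
                        placed_ok = True
                        break
                if not placed_ok:
                    layout_ok = False
                    break
            if layout_ok:
                break
        else:
            raise ValueError(
                f"could not place {n_lesions} lesions on a "
                f"{spec.slide_extent_mm} mm slide (tissue too small)")

    annotations = AnnotationSet(lesions=lesions)
    record = SlideRecord(
        slide_id=f"{spec.dataset_name}_{slide_index:04d}",
        dataset=spec.dataset_name,
        procedure=spec.procedure,
        gt_label=gt_label_from_diameters(annotations.diameters_mm()),
        annotation_status="full" if lesions else "none",
        spacing_um=sp,
    )
    return tissue, annotations, record


# --------------------------------------------------------------------------
# heatmap generation
# --------------------------------------------------------------------------


def _bounding_circle(polygon_um: np.ndarray) -> tuple[float, float, float]:
    c = polygon_um.mean(axis=0)
    r = float(np.max(np.hypot(polygon_um[:, 0] - c[0], polygon_um[:, 1] - c[1])))
    return float(c[0]), float(c[1]), r


def generate_heatmap(
    annotations: AnnotationSet,
    hspec: HeatmapSpec,
    extent_mm: tuple[float, float],
    spacing_um: float,
    seed: int | None = None,
    confounder_rate: float = 0.0,
) -> tuple[Heatmap, HeatmapTruth]:
    """Model-like heatmap: high scores in lesions, confounder FP blobs.

    Per-pixel scores are drawn from the spec's clipped-normal
    distributions.  Poisson-many confounder blobs (count ~
    Poisson(rate)) are placed so that they overlap neither lesions nor
    each other, each blob's pixels drawn from the FP score
    distribution.  Returns the heatmap and the planted truth (realized
    per-lesion and per-blob maximum scores) for enumeration oracles.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=hspec.seed if seed is None else seed))
    shape = (
        int(round(extent_mm[1] * 1000.0 / spacing_um)),
        int(round(extent_mm[0] * 1000.0 / spacing_um)),
    )
    values = hspec.background_score_dist.sample(rng, shape)

    lesion_label = annotations.rasterize(shape, spacing_um)
    lesion_max: list[float] = []
    for i in range(len(annotations)):
        sel = lesion_label == i + 1
        n = int(sel.sum())
        if n == 0:
            lesion_max.append(0.0)
            continue
        scores = hspec.in_lesion_score_dist.sample(rng, n)
        values[sel] = scores
        lesion_max.append(float(scores.max()))

    rate = hspec.fp_blob_rate if hspec.fp_blob_rate is not None else confounder_rate
    circles = [_bounding_circle(l.polygon_um) for l in annotations]
    blobs: list[FPBlob] = []
    n_blobs = int(rng.poisson(rate)) if rate > 0 else 0
    lo_mm, hi_mm = hspec.fp_blob_diameter_range_mm
    from skimage.draw import ellipse as draw_ellipse

    for _ in range(n_blobs):
        d_mm = float(rng.uniform(lo_mm, hi_mm))
        r_um = 0.5 * d_mm * 1000.0
        placed = False
        for _attempt in range(500):
            cx_um = rng.uniform(r_um + spacing_um,
                                extent_mm[0] * 1000.0 - r_um - spacing_um)
            cy_um = rng.uniform(r_um + spacing_um,
                                extent_mm[1] * 1000.0 - r_um - spacing_um)
            clear = all(
                np.hypot(cx_um - x, cy_um - y) > r_um + r + 2.0 * spacing_um
                for x, y, r in circles
            )
            if not clear:
                continue
            minor_um = 2.0 * r_um * rng.uniform(0.7, 1.0)
            theta = rng.uniform(0.0, np.pi)
            rr_b, cc_b = draw_ellipse(
                cy_um / spacing_um, cx_um / spacing_um,
                r_um / spacing_um, 0.5 * minor_um / spacing_um,
                shape=shape, rotation=theta,
            )
            scores = hspec.fp_blob_score_dist.sample(rng, len(rr_b))
            values[rr_b, cc_b] = scores
            blobs.append(FPBlob(cx_um, cy_um, d_mm, float(scores.max())))
            circles.append((cx_um, cy_um, r_um))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place a confounder blob without overlap; "
                "lower the rate or enlarge the slide")

    heatmap = Heatmap(values=values, spacing_um=spacing_um)
    return heatmap, HeatmapTruth(lesion_max_scores=lesion_max, fp_blobs=blobs)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


def simulate_slides(spec: CohortSpec, hspec: HeatmapSpec) -> Iterator[SlideSim]:
    """Lazily simulate every slide of a cohort (slide + heatmap + truth)."""
    for idx in range(spec.n_slides):
        tissue, annotations, record = generate_slide(spec, idx)
        hm_seed_seq = np.random.SeedSequence(
            entropy=hspec.seed, spawn_key=(1, spec.seed, idx))
        heatmap, truth = generate_heatmap(
            annotations, hspec, spec.slide_extent_mm, spec.raster_spacing_um,
            seed=hm_seed_seq.generate_state(1)[0] % (2 ** 31),
            confounder_rate=spec.confounder_rate,
        )
        yield SlideSim(record=record, tissue=tissue, annotations=annotations,
                       heatmap=heatmap, truth=truth)


def generate_cohort(
    specs: Sequence[CohortSpec],
    hspec: HeatmapSpec,
    output_dir,
    overwrite: bool = False,
) -> Manifest:
    """Write a full synthetic cohort to disk and return its manifest.

    Layout: ``manifest.csv``, ``truth.json``, and per-slide
    ``<id>_tissue.tif``, ``<id>_mask.tif`` (uint8 codes), ``<id>.xml``
    (ASAP-dialect annotations) and ``<id>_heatmap.tif`` (float32).
    """
    names = [s.dataset_name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("dataset names must be unique")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")

    records: list[SlideRecord] = []
    truth_index: dict[str, dict] = {}
    for spec in specs:
        for sim in simulate_slides(spec, hspec):
            sid = sim.record.slide_id
            tissue_path = out / f"{sid}_tissue.tif"
            mask_path = out / f"{sid}_mask.tif"
            ann_path = out / f"{sid}.xml"
            hm_path = out / f"{sid}_heatmap.tif"
            write_mask_tiff(tissue_path, (sim.tissue * 255).astype(np.uint8),
                            sim.record.spacing_um)
            write_mask_tiff(mask_path, sim.label_mask(), sim.record.spacing_um)
            sim.annotations.to_asap_xml(ann_path)
            sim.heatmap.write_tiff(hm_path)
            rec = sim.record
            rec.tissue_path = tissue_path.name
            rec.mask_path = mask_path.name
            rec.annotation_path = ann_path.name
            rec.heatmap_path = hm_path.name
            records.append(rec)
            truth_index[sid] = {
                "lesion_diameters_mm": sim.annotations.diameters_mm(),
                "lesion_max_scores": sim.truth.lesion_max_scores,
                "fp_blobs": [asdict(b) for b in sim.truth.fp_blobs],
            }
    manifest = Manifest(records, provenance="synthetic cohort")
    manifest.to_csv(out / "manifest.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_index, fh, indent=1, sort_keys=True)
    return manifest


# --------------------------------------------------------------------------
# patch sets
# --------------------------------------------------------------------------


def patch_extent_um(patch_px: int, spacing_um: float) -> float:
    """Physical side length of a square patch."""
    return patch_px * spacing_um


def generate_patch_set(
    slides: Sequence[tuple[np.ndarray, np.ndarray]],
    n_patches: int,
    tumor_fraction: float,
    patch_px: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample labelled patches from (tissue raster, label mask) pairs.

    Each patch's label is its center pixel's mask code (tumor for
    code 2, healthy for codes 1/3); the tumor/healthy mix is Bernoulli
    with probability ``tumor_fraction``, so the realized tumor count is
    binomial.  Returns ``(patches[n, p, p], labels[n])`` with label 1 =
    tumor.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    half = patch_px // 2

    tumor_pools = []
    healthy_pools = []
    for si, (tissue, mask) in enumerate(slides):
        if tissue.shape != mask.shape:
            raise ValueError("mask not aligned to tissue raster")
        interior = np.zeros_like(mask, dtype=bool)
        if mask.shape[0] > 2 * half and mask.shape[1] > 2 * half:
            interior[half:mask.shape[0] - half, half:mask.shape[1] - half] = True
        tumor_idx = np.argwhere((mask == CODE_TUMOR) & interior)
        healthy_idx = np.argwhere(
            ((mask == CODE_HEALTHY) | (mask == CODE_HARD_NEGATIVE)) & interior)
        if len(tumor_idx):
            tumor_pools.append((si, tumor_idx))
        if len(healthy_idx):
            healthy_pools.append((si, healthy_idx))

    if tumor_fraction > 0 and not tumor_pools:
        raise ValueError("no tumor pixels available but tumor_fraction > 0")
    if tumor_fraction < 1 and not healthy_pools:
        raise ValueError("no healthy pixels available but tumor_fraction < 1")

    patches = np.empty((n_patches, patch_px, patch_px), dtype=np.float32)
    labels = np.empty(n_patches, dtype=np.int64)
    for k in range(n_patches):
        is_tumor = rng.uniform() < tumor_fraction
        pools = tumor_pools if is_tumor else healthy_pools
        weights = np.array([len(p[1]) for p in pools], dtype=np.float64)
        si, idx = pools[rng.choice(len(pools), p=weights / weights.sum())]
        row, col = idx[rng.integers(len(idx))]
        tissue = slides[si][0]
        patches[k] = tissue[row - half: row - half + patch_px,
                            col - half: col - half + patch_px]
        labels[k] = 1 if is_tumor else 0
    return patches, labels
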