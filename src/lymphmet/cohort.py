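"""Study manifests: dataset composition, ITC exclusion, stratified splits.

The study pools slides from several sources (two local lymph-node sets,
one negative-only axillary set, and the two public CAMELYON sentinel-node
sets).  A manifest is an ordered collection of per-slide records carrying
the ground-truth TNM-derived label and the train/validation/test split.
Slides whose only finding is isolated tumor cells (ITC, ≤ 0.2 mm) are
node-negative under TNM and are excluded from the study before
splitting; the public datasets come with fixed, pre-generated splits
while the local datasets are split by stratified random sampling with
exact per-class counts.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from lymphmet.tnm import (
    LABEL_ITC_ONLY,
    LABEL_MACRO,
    LABEL_MICRO,
    LABEL_NEGATIVE,
    POSITIVE_LABELS,
)

SPLITS = ("train", "val", "test", "unassigned")

MANIFEST_COLUMNS = [
    "slide_id",
    "dataset",
    "procedure",
    "subtype",
    "gt_label",
    "split",
    "annotation_status",
    "enrichment",
    "spacing_um",
    "tissue_path",
    "mask_path",
    "annotation_path",
    "heatmap_path",
]


@dataclass
class SlideRecord:
    slide_id: str
    dataset: str
    procedure: str = "sentinel"  # sentinel | axillary
    subtype: str = "unknown"  # NST | ILC | unknown
    gt_label: str = LABEL_NEGATIVE  # negative | micro | macro | itc_only
    split: str = "unassigned"
    annotation_status: str = "none"  # full | partial | none
    enrichment: bool = False  # extra-nodal enrichment slide
    spacing_um: float = 0.5
    tissue_path: str = ""
    mask_path: str = ""
    annotation_path: str = ""
    heatmap_path: str = ""

    @property
    def is_positive(self) -> bool:
        return self.gt_label in POSITIVE_LABELS


class Manifest:
    """Ordered collection of slide records with unique ids."""

    def __init__(self, records: Iterable[SlideRecord] = (), provenance: str = ""):
        self.records: list[SlideRecord] = list(records)
        self.provenance = provenance
        ids = [r.slide_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate slide_id in manifest")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def subset(self, dataset: str | None = None, split: str | None = None) -> "Manifest":
        recs = [
            r
            for r in self.records
            if (dataset is None or r.dataset == dataset)
            and (split is None or r.split == split)
        ]
        return Manifest(recs, provenance=self.provenance)

    def count(self, dataset: str | None = None, split: str | None = None,
              positive: bool | None = None) -> int:
        n = 0
        for r in self.records:
            if dataset is not None and r.dataset != dataset:
                continue
            if split is not None and r.split != split:
                continue
            if positive is not None and r.is_positive != positive:
                continue
            n += 1
        return n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: getattr(r, c) for c in MANIFEST_COLUMNS} for r in self.records],
            columns=MANIFEST_COLUMNS,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Manifest":
        df = pd.read_csv(path, keep_default_na=False, dtype={"enrichment": str})
        records = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            d["enrichment"] = str(d.get("enrichment", "")).lower() in ("true", "1")
            d["spacing_um"] = float(d["spacing_um"])
            records.append(SlideRecord(**{k: d[k] for k in MANIFEST_COLUMNS}))
        return cls(records)


# --------------------------------------------------------------------------
# Composition -> manifest
# --------------------------------------------------------------------------


@dataclass
class DatasetComposition:
    """Counts describing one dataset, as published in the study tables.

    Where the micro/macro breakdown of positives is not published, the
    split between ``n_micro`` and ``n_macro`` is immaterial: only
    positive/negative status enters splitting and counting, so
    unspecified positives default to micro.
    """

    name: str
    procedure: str = "sentinel"
    n_negative: int = 0
    n_micro: int = 0
    n_macro: int = 0
    n_itc_only: int = 0
    n_enrichment: int = 0  # extra negative, extra-nodal-tissue slides
    n_partial_annotation: int = 0  # positives with partial annotations only
    spacing_um: float = 0.5
    #: Pre-generated split cells, split -> (n_negative, n_positive).
    fixed_splits: Mapping[str, tuple[int, int]] | None = None
    #: Fixed split counts for enrichment slides, split -> count.
    enrichment_splits: Mapping[str, int] | None = None

    @property
    def n_positive(self) -> int:
        return self.n_micro + self.n_macro

    def validate(self) -> None:
        counts = [
            self.n_negative, self.n_micro, self.n_macro, self.n_itc_only,
            self.n_enrichment, self.n_partial_annotation,
        ]
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.name}: negative count in composition")
        if self.n_partial_annotation > self.n_positive:
            raise ValueError(f"{self.name}: more partial annotations than positives")
        if self.fixed_splits is not None:
            neg = sum(v[0] for v in self.fixed_splits.values())
            pos = sum(v[1] for v in self.fixed_splits.values())
            if neg != self.n_negative or pos != self.n_positive:
                raise ValueError(f"{self.name}: fixed splits do not sum to totals")
        if self.enrichment_splits is not None:
            if sum(self.enrichment_splits.values()) != self.n_enrichment:
                raise ValueError(f"{self.name}: enrichment splits do not sum")


def build_manifest(compositions: Sequence[DatasetComposition]) -> Manifest:
    """One slide record per described slide; splits fixed where published.

    Records of datasets without pre-generated splits are returned with
    ``split='unassigned'`` for :func:`stratified_split`.  ITC-only
    records are always unassigned (they are excluded before splitting).
    """
    names = [c.name for c in compositions]
    if len(set(names)) != len(names):
        raise ValueError("duplicate dataset names")
    records: list[SlideRecord] = []
    for comp in compositions:
        comp.validate()
        fixed_neg: list[str] = []
        fixed_pos: list[str] = []
        if comp.fixed_splits is not None:
            for split, (n_neg, n_pos) in comp.fixed_splits.items():
                fixed_neg.extend([split] * n_neg)
                fixed_pos.extend([split] * n_pos)
        fixed_enr: list[str] = []
        if comp.enrichment_splits is not None:
            for split, n in comp.enrichment_splits.items():
                fixed_enr.extend([split] * n)

        i = 0

        def make(label, split="unassigned", annotation_status="none",
                 enrichment=False):
            nonlocal i
            rec = SlideRecord(
                slide_id=f"{comp.name}_{i:04d}",
                dataset=comp.name,
                procedure=comp.procedure,
                gt_label=label,
                split=split,
                annotation_status=annotation_status,
                enrichment=enrichment,
                spacing_um=comp.spacing_um,
            )
            i += 1
            return rec

        for k in range(comp.n_negative):
            split = fixed_neg[k] if fixed_neg else "unassigned"
            records.append(make(LABEL_NEGATIVE, split))
        for k in range(comp.n_enrichment):
            split = fixed_enr[k] if fixed_enr else "unassigned"
            records.append(make(LABEL_NEGATIVE, split, enrichment=True))
        pos_labels = [LABEL_MICRO] * comp.n_micro + [LABEL_MACRO] * comp.n_macro
        for k, label in enumerate(pos_labels):
            split = fixed_pos[k] if fixed_pos else "unassigned"
            status = "partial" if k < comp.n_partial_annotation else "full"
            records.append(make(label, split, annotation_status=status))
        for _ in range(comp.n_itc_only):
            records.append(make(LABEL_ITC_ONLY, annotation_status="full"))
    return Manifest(records, provenance="built from dataset compositions")


def exclude_itc(manifest: Manifest) -> Manifest:
    """Drop ITC-only slides; order of remaining records preserved. Idempotent."""
    return Manifest(
        [r for r in manifest if r.gt_label != LABEL_ITC_ONLY],
        provenance=manifest.provenance,
    )


def stratified_split(
    manifest: Manifest,
    targets: Mapping[str, Mapping[str, tuple[int, int]]],
    seed: int,
    enrichment_targets: Mapping[str, Mapping[str, int]] | None = None,
) -> Manifest:
    """Assign exact per-class split counts by random sampling.

    ``targets[dataset][split] = (n_negative, n_positive)`` for the
    non-enrichment, currently unassigned records of each listed dataset;
    ``enrichment_targets[dataset][split] = n`` for enrichment slides.
    Records already carrying a split (pre-generated public splits) are
    untouched.  Counts must exactly exhaust each class or the targets
    are rejected as infeasible.
    """
    rng = np.random.default_rng(seed)
    new_records = list(manifest.records)
    enrichment_targets = enrichment_targets or {}

    for dataset, split_targets in targets.items():
        for positive in (False, True):
            idx = [
                k
                for k, r in enumerate(new_records)
                if r.dataset == dataset
                and r.split == "unassigned"
                and not r.enrichment
                and r.gt_label != LABEL_ITC_ONLY
                and r.is_positive == positive
            ]
            wanted = {s: c[1 if positive else 0] for s, c in split_targets.items()}
            total = sum(wanted.values())
            if total != len(idx):
                cls = "positive" if positive else "negative"
                raise ValueError(
                    f"{dataset}: {cls} targets sum to {total}, "
                    f"but {len(idx)} records are available"
                )
            perm = rng.permutation(len(idx))
            pos = 0
            for split, n in wanted.items():
                for j in perm[pos:pos + n]:
                    new_records[idx[j]] = replace(new_records[idx[j]], split=split)
                pos += n

    for dataset, split_targets in enrichment_targets.items():
        idx = [
            k
            for k, r in enumerate(new_records)
            if r.dataset == dataset and r.split == "unassigned" and r.enrichment
        ]
        total = sum(split_targets.values())
        if total != len(idx):
            raise ValueError(
                f"{dataset}: enrichment targets sum to {total}, "
                f"but {len(idx)} enrichment records are available"
            )
        perm = rng.permutation(len(idx))
        pos = 0
        for split, n in split_targets.items():
            for j in perm[pos:pos + n]:
                new_records[idx[j]] = replace(new_records[idx[j]], split=split)
            pos += n

    return Manifest(new_records, provenance=manifest.provenance)


# --------------------------------------------------------------------------
# The study's published composition (inputs to the manifest builder)
# --------------------------------------------------------------------------

#: Composition of the five data sources.  The CAMELYON16 splits are the
#: organizers' pre-generated splits; CAMELYON17's allocation of its 50
#: negative training and 260 negative test slides (plus 15/9/10 annotated
#: positives) is likewise fixed.  CAMELYON17's 50 annotated positives
#: include 16 ITC-only slides that the study excludes.
STUDY_COMPOSITIONS: tuple[DatasetComposition, ...] = (
    DatasetComposition(
        name="LocalSentinel",
        procedure="sentinel",
        n_negative=107,
        n_micro=54,
    ),
    DatasetComposition(
        name="LocalAxillary",
        procedure="axillary",
        n_negative=24,
        n_micro=24,
        n_enrichment=9,
    ),
    DatasetComposition(
        name="CAMELYON16",
        procedure="sentinel",
        n_negative=239,
        n_micro=160,
        n_partial_annotation=20,
        fixed_splits={"train": (127, 89), "val": (32, 22), "test": (80, 49)},
    ),
    DatasetComposition(
        name="CAMELYON17",
        procedure="sentinel",
        n_negative=310,
        n_micro=34,
        n_itc_only=16,
        fixed_splits={"train": (40, 15), "val": (10, 9), "test": (260, 10)},
    ),
)

#: Negative-only axillary evaluation set, kept outside the train/val/test
#: accounting (evaluation of false-positive rates only).
NEGATIVE_AXILLARY_COMPOSITION = DatasetComposition(
    name="LocalNegativeAxillary",
    procedure="axillary",
    n_negative=259,
)

#: Stratified split targets for the two local datasets,
#: dataset -> split -> (n_negative, n_positive).
STUDY_SPLIT_TARGETS: dict[str, dict[str, tuple[int, int]]] = {
    "LocalSentinel": {"train": (58, 30), "val": (15, 7), "test": (34, 17)},
    "LocalAxillary": {"train": (11, 13), "val": (3, 4), "test": (10, 7)},
}

#: The nine extra-nodal enrichment slides go 6 to train, 3 to val.
STUDY_ENRICHMENT_TARGETS: dict[str, dict[str, int]] = {
    "LocalAxillary": {"train": 6, "val": 3},
}


def build_study_manifest(seed: int = 0, include_negative_axillary: bool = False
                         ) -> Manifest:
    """Full study manifest: build, exclude ITC-only slides, split."""
    comps = list(STUDY_COMPOSITIONS)
    if include_negative_axillary:
        comps.append(NEGATIVE_AXILLARY_COMPOSITION)
    manifest = build_manifest(comps)
    manifest = exclude_itc(manifest)
    return stratified_split(
        manifest, STUDY_SPLIT_TARGETS, seed=seed,
        enrichment_targets=STUDY_ENRICHMENT_TARGETS,
    )
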