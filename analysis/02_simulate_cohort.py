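#!/usr/bin/env python
"""Simulate a synthetic slide cohort and write it to disk.

Generates a 20-negative / 20-positive cohort with confounder blobs at
one per slide (tissue rasters, code masks, ASAP-dialect lesion
annotations, tumor-probability heatmaps), the stand-in for the clinical
archives.  Binary rasters go to scratch/; the manifest and a composition
summary go to results/.
"""

import json
import shutil
from pathlib import Path

from lymphmet.synthetic import CohortSpec, HeatmapSpec, generate_cohort

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "cohort"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    shutil.rmtree(SCRATCH, ignore_errors=True)
    spec = CohortSpec(
        dataset_name="SimSentinel",
        n_negative=20,
        n_positive=20,
        slide_extent_mm=(10.0, 10.0),
        raster_spacing_um=16.0,
        macro_diameter_mm=(2.5, 4.0),
        confounder_rate=1.0,
        seed=42,
    )
    hspec = HeatmapSpec(seed=43)
    manifest = generate_cohort([spec], hspec, SCRATCH)
    manifest.to_csv(RESULTS / "sim_cohort_manifest.csv")

    labels = {}
    for rec in manifest:
        labels[rec.gt_label] = labels.get(rec.gt_label, 0) + 1
    summary = {
        "n_slides": len(manifest),
        "labels": labels,
        "raster_px": spec.raster_shape(),
        "raster_spacing_um": spec.raster_spacing_um,
    }
    with open(RESULTS / "sim_cohort_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    print(f"Simulated {len(manifest)} slides into {SCRATCH}")
    print("Ground-truth label counts:", labels)


if __name__ == "__main__":
    main()
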