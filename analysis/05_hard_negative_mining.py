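#!/usr/bin/env python
"""Hard negative mining over a confounder-rich synthetic cohort.

Simulates slides whose heatmaps carry confounder false-positive blobs,
runs the mining protocol (threshold 0.5, regions > 0.2 mm, no overlap
with ground truth), and summarizes how much healthy tissue each slide's
label mask re-codes as hard negative (code 3).
"""

import json
from pathlib import Path

import numpy as np

from lymphmet.hnm import mine_and_update, mine_hard_negatives
from lymphmet.synthetic import CohortSpec, HeatmapSpec, simulate_slides

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = CohortSpec(dataset_name="mine", n_negative=6, n_positive=6,
                      slide_extent_mm=(8.0, 8.0), raster_spacing_um=16.0,
                      macro_diameter_mm=(2.5, 3.5), seed=7)
    hspec = HeatmapSpec(fp_blob_rate=4.0, seed=8)

    rows = []
    for sim in simulate_slides(spec, hspec):
        regions = mine_hard_negatives(sim.heatmap, sim.annotations)
        mask = mine_and_update(sim.heatmap, sim.annotations, sim.tissue,
                               sim.record.spacing_um)
        rows.append({
            "slide_id": sim.record.slide_id,
            "gt_label": sim.record.gt_label,
            "planted_confounders": len(sim.truth.fp_blobs),
            "mined_regions": len(regions),
            "code3_pixels": int((mask.codes == 3).sum()),
            "code2_pixels": int((mask.codes == 2).sum()),
        })

    mined = sum(r["mined_regions"] for r in rows)
    planted = sum(r["planted_confounders"] for r in rows)
    print(f"{planted} confounder blobs planted, {mined} regions mined "
          "(equal because confounders never touch ground truth and all "
          "exceed 0.2 mm).")
    for r in rows[:4]:
        print(f"  {r['slide_id']} [{r['gt_label']}]: "
              f"{r['mined_regions']} regions -> {r['code3_pixels']} code-3 px")
    with open(RESULTS / "hnm_summary.json", "w") as fh:
        json.dump(rows, fh, indent=1)
    print(f"Wrote {RESULTS / 'hnm_summary.json'}")


if __name__ == "__main__":
    main()
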