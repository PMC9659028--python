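#!/usr/bin/env python
"""Build the study manifest from the published dataset tables.

Constructs every dataset's slide records, removes the ITC-only slides
(node-negative under TNM, out of study scope), applies the fixed public
splits and the stratified random splits for the local datasets, and
writes the manifest plus its marginal counts.
"""

import json
from pathlib import Path

from lymphmet.cohort import build_study_manifest

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    study = build_study_manifest(seed=0)
    study.to_csv(RESULTS / "study_manifest.csv")

    counts = {}
    for dataset in ("CAMELYON16", "CAMELYON17", "LocalSentinel",
                    "LocalAxillary"):
        counts[dataset] = {
            "total": study.count(dataset),
            "negative": study.count(dataset, positive=False),
            "positive": study.count(dataset, positive=True),
            "train": study.count(dataset, "train"),
            "val": study.count(dataset, "val"),
            "test": study.count(dataset, "test"),
        }
    counts["total"] = {
        "total": len(study),
        "train": study.count(split="train"),
        "val": study.count(split="val"),
        "test": study.count(split="test"),
    }
    counts["combined_local_test"] = (
        study.count("LocalSentinel", "test")
        + study.count("LocalAxillary", "test"))
    with open(RESULTS / "manifest_counts.json", "w") as fh:
        json.dump(counts, fh, indent=1)

    print(f"Study manifest: {len(study)} slides "
          f"({study.count(positive=True)} positive).")
    print(f"CAMELYON17 after ITC exclusion: {study.count('CAMELYON17')}.")
    print("Combined local test set:", counts["combined_local_test"], "slides.")
    print(f"Wrote {RESULTS / 'study_manifest.csv'} and manifest_counts.json")


if __name__ == "__main__":
    main()
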