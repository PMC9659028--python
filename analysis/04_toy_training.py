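#!/usr/bin/env python
"""Train scaled-down networks on synthetic patches.

Runs the three retraining strategies at toy scale on simulated slides
(a local axillary source and a pooled sentinel source): scratch on
pooled data, scratch with local upweighting, and fine-tuning the base
checkpoint on local data with hard negative mining enabled.  Writes the
per-epoch histories; the point is the machinery (plateau schedule,
sampler composition, checkpointing), not the toy accuracies.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lymphmet.network import NetworkConfig, build_network
from lymphmet.synthetic import CohortSpec, perfect_heatmap_spec, simulate_slides
from lymphmet.training import (
    SlideSource,
    StrategyConfig,
    TrainConfig,
    run_strategy,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

NET = NetworkConfig(n_dense_blocks=1, convs_1x1_per_block=3,
                    convs_3x3_per_block=2, channels_1x1=8, channels_3x3=4,
                    patch_px=9, in_channels=1)


def sources():
    out = []
    for name, local, seed in (("sentinel", False, 10), ("axillary", True, 11)):
        spec = CohortSpec(dataset_name=name, n_negative=1, n_positive=2,
                          slide_extent_mm=(4.0, 4.0), raster_spacing_um=16.0,
                          macro_diameter_mm=(2.2, 2.6), seed=seed)
        for sim in simulate_slides(spec, perfect_heatmap_spec()):
            out.append(SlideSource(slide_id=sim.record.slide_id,
                                   tissue=sim.tissue, mask=sim.label_mask(),
                                   local=local))
    return out


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = TrainConfig(lr_init=1e-3, max_epochs=8, patches_per_epoch=256,
                      patch_px=9, batch_size=32, augment=False,
                      early_stop_patience=6, lr_patience_epochs=3, seed=1)
    srcs = sources()

    strategies = {
        "scratch_uniform": StrategyConfig(),
        "scratch_upweighted": StrategyConfig(
            sampling_mode="local_upweighted", local_upweight_factor=4.0),
    }
    histories = []
    base_state = None
    for name, strategy in strategies.items():
        net, hist = run_strategy(None, srcs, strategy, cfg, NET,
                                 val_patches=128)
        hist["strategy"] = name
        histories.append(hist)
        if name == "scratch_uniform":
            base_state = net.get_state()
        print(f"{name}: {len(hist)} epochs, "
              f"best val acc {hist.val_acc.max():.3f}")

    finetune = StrategyConfig(transfer_mode="finetune_local",
                              hnm_enabled=True, hnm_code_sampling_weight=4.0)
    net, hist = run_strategy(base_state, srcs, finetune, cfg, NET,
                             val_patches=128)
    hist["strategy"] = "finetune_local_hnm"
    histories.append(hist)
    print(f"finetune_local_hnm: {len(hist)} epochs, "
          f"best val acc {hist.val_acc.max():.3f}")

    pd.concat(histories).to_csv(RESULTS / "training_history.csv", index=False)
    print(f"Wrote {RESULTS / 'training_history.csv'}")


if __name__ == "__main__":
    main()
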