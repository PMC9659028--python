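"""Fully convolutional whole-slide inference.

With valid padding, patchwise and fully convolutional application agree
exactly, so a slide can be processed in tiles with the right overlap and
the tiling is invisible in the output.  The heatmap grid has spacing
``input spacing × output stride`` and is offset by half the field of
view, so each heatmap pixel sits at the center of its receptive field.
Non-tissue positions are zeroed.
"""

from __future__ import annotations

import numpy as np

from lymphmet.heatmap import Heatmap
from lymphmet.network.densenet import DenseNet
from lymphmet.synthetic import TISSUE_THRESHOLD


def predict_slide(
    tissue: np.ndarray,
    network: DenseNet,
    spacing_um: float,
    tile_px: int = 1024,
    tissue_threshold: float = TISSUE_THRESHOLD,
    trained_spacing_um: float | None = None,
    spacing_rtol: float = 0.02,
) -> Heatmap:
    """Tumor-probability heatmap for one tissue raster.

    ``tissue`` is (H, W) or (H, W, C); a single channel is replicated to
    the network's input channels.  ``tile_px`` bounds the input-tile
    side; any tiling yields the identical heatmap.  If
    ``trained_spacing_um`` is given, a raster spacing deviating by more
    than ``spacing_rtol`` is rejected.
    """
    if trained_spacing_um is not None:
        if abs(spacing_um - trained_spacing_um) > spacing_rtol * trained_spacing_um:
            raise ValueError(
                f"raster spacing {spacing_um} differs from the training "
                f"spacing {trained_spacing_um}")
    tissue = np.asarray(tissue, dtype=np.float32)
    c = network.config.in_channels
    if tissue.ndim == 2:
        x_full = np.repeat(tissue[..., None], c, axis=-1)
        tissue_value = tissue
    elif tissue.ndim == 3:
        if tissue.shape[-1] != c:
            raise ValueError(
                f"raster has {tissue.shape[-1]} channels, network expects {c}")
        x_full = tissue
        tissue_value = tissue.mean(axis=-1)
    else:
        raise ValueError("tissue raster must be 2-D or 3-D")

    h, w = tissue_value.shape
    out_h, out_w, stride = network.output_shape(h, w)
    fov = network.min_input

    tile_out = max(1, (max(tile_px, fov) - fov) // stride + 1)
    heat = np.empty((out_h, out_w), dtype=np.float32)
    for oi in range(0, out_h, tile_out):
        oi_end = min(oi + tile_out, out_h)
        a_r = oi * stride
        b_r = (oi_end - 1) * stride + fov
        for oj in range(0, out_w, tile_out):
            oj_end = min(oj + tile_out, out_w)
            a_c = oj * stride
            b_c = (oj_end - 1) * stride + fov
            probs = network.forward(x_full[None, a_r:b_r, a_c:b_c, :])
            block = probs[0, :, :, 1]
            if block.shape != (oi_end - oi, oj_end - oj):
                raise AssertionError("tile output shape mismatch")
            heat[oi:oi_end, oj:oj_end] = block

    center = (fov - 1) // 2
    rows = np.arange(out_h) * stride + center
    cols = np.arange(out_w) * stride + center
    mask = tissue_value[np.ix_(rows, cols)] > tissue_threshold
    heat[~mask] = 0.0

    return Heatmap(
        values=heat,
        spacing_um=spacing_um * stride,
        offset_um=((fov - 1) / 2.0 * spacing_um, (fov - 1) / 2.0 * spacing_um),
    )
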