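"""Tumor-probability heatmaps with physical pixel spacing.

A heatmap is a single-channel float raster of tumor-class probabilities
in [0, 1] on a regular grid.  ``spacing_um`` is the grid pitch in
micrometers and ``offset_um`` the (x, y) position of the center of pixel
(row 0, col 0) in slide coordinates (micrometers, origin top-left,
x right, y down).  Fully convolutional inference with valid padding
produces a grid that is both strided and offset relative to the slide,
hence both fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class Heatmap:
    values: np.ndarray  # (H, W) float32 in [0, 1]
    spacing_um: float
    offset_um: tuple[float, float] = (0.0, 0.0)  # (x, y) of pixel (0, 0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("heatmap raster must be 2-D")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_to_um(self, rows: np.ndarray, cols: np.ndarray):
        """Map (row, col) pixel indices to (x, y) slide micrometers."""
        x = self.offset_um[0] + np.asarray(cols) * self.spacing_um
        y = self.offset_um[1] + np.asarray(rows) * self.spacing_um
        return x, y

    def write_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            self.values,
            tile=(256, 256) if min(self.values.shape) >= 256 else None,
            metadata={
                "spacing_um": self.spacing_um,
                "offset_um": list(self.offset_um),
            },
        )

    @classmethod
    def read_tiff(cls, path) -> "Heatmap":
        with tifffile.TiffFile(path) as tif:
            values = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        spacing = float(meta.get("spacing_um", 0.0))
        if spacing <= 0:
            raise ValueError(f"{path}: missing spacing metadata")
        offset = tuple(meta.get("offset_um", (0.0, 0.0)))
        return cls(values=values, spacing_um=spacing, offset_um=offset)


def write_mask_tiff(path, mask: np.ndarray, spacing_um: float) -> None:
    """Write a uint8 label mask with spacing metadata."""
    mask = np.asarray(mask, dtype=np.uint8)
    tifffile.imwrite(
        path,
        mask,
        tile=(256, 256) if min(mask.shape) >= 256 else None,
        metadata={"spacing_um": spacing_um},
    )


def read_mask_tiff(path) -> tuple[np.ndarray, float]:
    with tifffile.TiffFile(path) as tif:
        mask = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    spacing = float(meta.get("spacing_um", 0.0))
    if spacing <= 0:
        raise ValueError(f"{path}: missing spacing metadata")
    return mask.astype(np.uint8), spacing
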