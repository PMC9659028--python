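"""Patch augmentation stack.

Transforms are applied in a fixed order — horizontal flip, rotation
(quarter turns), scaling [0.9, 1.1], hue [−0.1, 0.1], saturation
[−0.25, 0.25], brightness [−0.25, 0.25], contrast [−0.25, 0.25],
Gaussian noise sd [0, 0.05], Gaussian blur sd [0, 1.0] — with
parameters drawn uniformly from those ranges/sets.  Hue and saturation
are fractional offsets in HSV space; brightness is additive and
contrast multiplicative in RGB.  Scaling resamples and then
center-crops (or edge-pads) back to the original size so the patch
shape never changes; the label never changes either.  Output is
clipped to [0, 1].  Each parameter at its identity value leaves the
patch bit-for-bit unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage import transform
from skimage.color import hsv2rgb, rgb2hsv


@dataclass
class AugmentParams:
    flip: bool = False
    rot_quarters: int = 0  # number of 90° counter-clockwise turns
    scale: float = 1.0
    hue: float = 0.0
    saturation: float = 0.0
    brightness: float = 0.0
    contrast: float = 0.0
    noise_sd: float = 0.0
    blur_sd: float = 0.0
    noise_seed: int = 0

    @classmethod
    def draw(cls, rng: np.random.Generator) -> "AugmentParams":
        return cls(
            flip=bool(rng.integers(2)),
            rot_quarters=int(rng.integers(4)),
            scale=float(rng.uniform(0.9, 1.1)),
            hue=float(rng.uniform(-0.1, 0.1)),
            saturation=float(rng.uniform(-0.25, 0.25)),
            brightness=float(rng.uniform(-0.25, 0.25)),
            contrast=float(rng.uniform(-0.25, 0.25)),
            noise_sd=float(rng.uniform(0.0, 0.05)),
            blur_sd=float(rng.uniform(0.0, 1.0)),
            noise_seed=int(rng.integers(2 ** 31)),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _resize_keep_shape(patch: np.ndarray, scale: float) -> np.ndarray:
    h, w = patch.shape[:2]
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    resized = transform.resize(
        patch, (nh, nw) + patch.shape[2:], order=1, mode="edge",
        anti_aliasing=scale < 1.0, preserve_range=True,
    ).astype(np.float32)
    if nh >= h:
        oh, ow = (nh - h) // 2, (nw - w) // 2
        return resized[oh:oh + h, ow:ow + w]
    ph, pw = h - nh, w - nw
    pad = [(ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)]
    pad += [(0, 0)] * (patch.ndim - 2)
    return np.pad(resized, pad, mode="edge")


def augment(patch: np.ndarray, params: AugmentParams) -> np.ndarray:
    """Apply the stack with the given parameter draw (label-preserving)."""
    out = np.asarray(patch, dtype=np.float32)
    shape = out.shape
    if params.flip:
        out = out[:, ::-1].copy()
    if params.rot_quarters % 4:
        out = np.rot90(out, k=params.rot_quarters % 4, axes=(0, 1)).copy()
    if params.scale != 1.0:
        out = _resize_keep_shape(out, params.scale)
    if (params.hue != 0.0 or params.saturation != 0.0) and out.ndim == 3 \
            and out.shape[-1] == 3:
        hsv = rgb2hsv(np.clip(out, 0.0, 1.0))
        hsv[..., 0] = (hsv[..., 0] + params.hue) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + params.saturation, 0.0, 1.0)
        out = hsv2rgb(hsv).astype(np.float32)
    if params.brightness != 0.0:
        out = out + params.brightness
    if params.contrast != 0.0:
        out = out * (1.0 + params.contrast)
    if params.noise_sd > 0.0:
        noise_rng = np.random.default_rng(params.noise_seed)
        out = out + noise_rng.normal(0.0, params.noise_sd, size=out.shape)
    if params.blur_sd > 0.0:
        sigma = (params.blur_sd, params.blur_sd) + (0.0,) * (out.ndim - 2)
        out = ndimage.gaussian_filter(out, sigma)
    out = np.clip(out, 0.0, 1.0).astype(np.float32)
    if out.shape != shape and params.rot_quarters % 2 == 0:
        raise AssertionError("augmentation changed the patch shape")
    return out


def augment_random(patch: np.ndarray, rng: np.random.Generator
                   ) -> tuple[np.ndarray, AugmentParams]:
    """Draw parameters and apply; returns the draw for logging."""
    params = AugmentParams.draw(rng)
    return augment(patch, params), params
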