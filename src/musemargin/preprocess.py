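"""Per-tile illumination correction and post-stitch contrast enhancement.

A single oblique deep-UV LED illuminates each field of view unevenly, which
shows up as smooth multiplicative shading in every tile.  Correction runs in
hue-saturation-value space so that the colour information (hue) carried by
the two-stain fluorescence split is preserved: a smooth gain field is
estimated for the saturation and value channels from the tile stack itself
(per-pixel median across tiles, heavy Gaussian smoothing, normalisation to
mean 1) and divided out per tile.

After stitching, global histogram equalization of the R and G channels
enhances visual contrast; the B channel is left untouched.  Equalization is
computed over in-tissue pixels (value channel above a small floor) so the
dark background does not dominate the histogram, and is applied as a single
monotone lookup table so pixel rank ordering within each channel is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import color

from .phantom import ShadingField

__all__ = [
    "HsvShading",
    "rgb_to_hsv",
    "hsv_to_rgb",
    "estimate_shading",
    "correct_shading",
    "equalize_rg",
]

#: Gaussian smoothing sigma for shading estimation, fraction of tile width.
DEFAULT_SHADING_SIGMA_FRAC = 0.125

#: Value-channel floor (fraction of range) defining "in tissue" pixels.
DEFAULT_EQUALIZE_FLOOR = 0.02


@dataclass
class HsvShading:
    """Multiplicative gain fields for the saturation and value channels."""

    s: ShadingField
    v: ShadingField


def _as_float(image: np.ndarray) -> tuple[np.ndarray, type, int]:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if np.issubdtype(img.dtype, np.integer):
        maxv = np.iinfo(img.dtype).max
        return img.astype(np.float64) / maxv, img.dtype.type, maxv
    return img.astype(np.float64), img.dtype.type, 1


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """RGB (integer or float) to float HSV in [0, 1] per channel."""
    f, _, _ = _as_float(image)
    return color.rgb2hsv(f)


def hsv_to_rgb(hsv: np.ndarray, dtype=np.uint8) -> np.ndarray:
    """Float HSV back to RGB at the requested integer bit depth."""
    rgb = color.hsv2rgb(np.clip(hsv, 0.0, 1.0))
    if np.issubdtype(np.dtype(dtype), np.integer):
        maxv = np.iinfo(dtype).max
        return np.clip(np.rint(rgb * maxv), 0, maxv).astype(dtype)
    return rgb.astype(dtype)


def estimate_shading(
    tiles: list[np.ndarray],
    sigma_frac: float = DEFAULT_SHADING_SIGMA_FRAC,
) -> HsvShading:
    """Estimate S and V shading gains from a stack of raw tiles.

    The per-pixel median across tiles suppresses tissue structure (which
    moves from tile to tile) while retaining the static illumination
    pattern; heavy Gaussian smoothing removes the residual texture and the
    result is normalised to spatial mean 1.

    Requires at least 4 tiles — with fewer, the median retains too much
    tissue structure to be a credible illumination estimate.
    """
    if len(tiles) < 4:
        raise ValueError(
            f"shading estimation needs at least 4 tiles, got {len(tiles)}"
        )
    shape = tiles[0].shape
    if any(t.shape != shape for t in tiles):
        raise ValueError("all tiles must share one shape")
    sv = np.stack(
        [rgb_to_hsv(t)[:, :, 1:] for t in tiles], axis=0
    )  # (n, H, W, 2)
    med = np.median(sv, axis=0)
    sigma = sigma_frac * shape[1]
    fields = []
    for k in range(2):
        f = gaussian_filter(med[:, :, k], sigma=sigma, mode="nearest")
        f = np.maximum(f, 1e-6)
        fields.append(ShadingField(gain=f / f.mean()))
    return HsvShading(s=fields[0], v=fields[1])


def correct_shading(tile: np.ndarray, field: HsvShading) -> np.ndarray:
    """Divide the tile's S and V channels by their gain fields.

    Hue is untouched; S and V are clipped back to [0, 1] after division and
    the result is re-quantised to the input bit depth.  With identity fields
    the output equals the input.
    """
    img = np.asarray(tile)
    if field.s.gain.shape != img.shape[:2] or field.v.gain.shape != img.shape[:2]:
        raise ValueError("shading field shape does not match the tile")
    hsv = rgb_to_hsv(img)
    hsv[:, :, 1] = np.clip(hsv[:, :, 1] / field.s.gain, 0.0, 1.0)
    hsv[:, :, 2] = np.clip(hsv[:, :, 2] / field.v.gain, 0.0, 1.0)
    return hsv_to_rgb(hsv, dtype=img.dtype if np.issubdtype(img.dtype, np.integer) else np.uint8)


def _equalize_channel(channel: np.ndarray, mask: np.ndarray, maxv: int) -> np.ndarray:
    """Histogram-equalize one integer channel via a monotone LUT built on
    the masked pixels; degenerate (single-valued) histograms are left
    unchanged."""
    sel = channel[mask] if mask.any() else channel.ravel()
    values = np.unique(sel)
    if len(values) <= 1:
        return channel.copy()
    hist = np.bincount(sel.ravel(), minlength=maxv + 1).astype(np.float64)
    cdf = np.cumsum(hist)
    cdf /= cdf[-1]
    lut = np.clip(np.rint(cdf * maxv), 0, maxv).astype(channel.dtype)
    return lut[channel]


def equalize_rg(
    mosaic: np.ndarray, floor: float = DEFAULT_EQUALIZE_FLOOR
) -> np.ndarray:
    """Global histogram equalization of the R and G channels; B unchanged.

    The histogram is computed over pixels whose value channel (per-pixel
    channel maximum) exceeds ``floor`` of the intensity range, then the
    resulting monotone lookup table is applied to every pixel.
    """
    img = np.asarray(mosaic)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB mosaic")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError("equalization expects an integer-typed mosaic")
    maxv = np.iinfo(img.dtype).max
    v = img.max(axis=2).astype(np.float64) / maxv
    mask = v > floor
    out = img.copy()
    for ch in (0, 1):
        out[:, :, ch] = _equalize_channel(img[:, :, ch], mask, maxv)
    return out
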