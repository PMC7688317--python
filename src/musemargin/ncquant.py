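"""Nuclei segmentation and patch-level nuclear-to-cytoplasm (N/C) scoring.

Propidium-iodide-stained nuclei emit in the yellow-red band, so segmentation
works on the red channel of the stitched, contrast-enhanced mosaic.  The
segmenter combines edge detection and intensity thresholding: a Sobel
gradient magnitude thresholded adaptively (k x the RMS gradient) finds
nucleus contours, morphological closing and hole filling turn the contours
into solid blobs, and an intensity threshold — 70% of the mean of the 1%
brightest pixels — removes texture that is edged but not bright.

The binary mask is then scored in two stages: non-overlapping small patches
of 198x198 px (250x250 um at the default pitch) each get N/C = white pixels
/ patch pixels; neighbouring 8x8 blocks of small patches are averaged into
large patches of 2x2 mm, the pitch at which standard breast pathology
samples.  Large patches in which more than half (i.e. more than 32) of the
small patches contain no cells at all are excluded — they sit on the tissue
boundary and would dilute the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import binary_fill_holes
from skimage.filters import sobel
from skimage.morphology import closing, disk

__all__ = [
    "NuclearMask",
    "SmallPatchGrid",
    "intensity_threshold",
    "segment_nuclei",
    "nc_small_patches",
    "merge_large_patches",
    "label_patches",
]

DEFAULT_PATCH_PX = 198
DEFAULT_BLOCK = 8
DEFAULT_ZERO_LIMIT = 32
DEFAULT_EDGE_K = 2.0
DEFAULT_CLOSING_RADIUS = 3
DEFAULT_THRESHOLD_FRACTION = 0.70
DEFAULT_TOP_PERCENT = 1.0


@dataclass
class NuclearMask:
    """Binary nuclei mask plus the parameters that produced it."""

    mask: np.ndarray  # bool, same shape as the source red channel
    intensity_threshold: float
    edge_threshold: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class SmallPatchGrid:
    """Per-patch N/C over a non-overlapping tiling anchored at the origin.

    ``nc[r, c] = whites[r, c] / counts[r, c]``; edge patches that do not
    span a full window are scored over their actual pixel count and flagged
    ``partial``.
    """

    patch_px: int
    nc: np.ndarray  # float, (rows, cols)
    whites: np.ndarray  # int, white-pixel count per patch
    counts: np.ndarray  # int, total pixels per patch
    partial: np.ndarray  # bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.nc.shape

    def origin_px(self, row: int, col: int) -> tuple[int, int]:
        """Top-left (x0, y0) of patch (row, col)."""
        return col * self.patch_px, row * self.patch_px


def intensity_threshold(
    red_channel: np.ndarray,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    top_percent: float = DEFAULT_TOP_PERCENT,
) -> float:
    """Threshold = ``fraction`` x mean of the ``top_percent`` brightest pixels.

    The brightest 1% is taken by value: the cutoff is the value at the
    (100 - top_percent) percentile position and every pixel tied with it is
    included.  An all-zero image yields threshold 0.
    """
    flat = np.asarray(red_channel, dtype=np.float64).ravel()
    if flat.size == 0:
        raise ValueError("empty channel")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if not 0.0 < top_percent <= 100.0:
        raise ValueError("top_percent must lie in (0, 100]")
    k = max(1, int(np.ceil(flat.size * top_percent / 100.0)))
    cutoff = np.partition(flat, flat.size - k)[flat.size - k]
    top = flat[flat >= cutoff]
    return float(fraction * top.mean())


def segment_nuclei(
    red_channel: np.ndarray,
    edge_k: float = DEFAULT_EDGE_K,
    closing_radius: int = DEFAULT_CLOSING_RADIUS,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    top_percent: float = DEFAULT_TOP_PERCENT,
) -> NuclearMask:
    """Segment nuclei by hybrid edge detection + intensity thresholding.

    ``mask = fill(close(|Sobel| > edge_k * RMS gradient)) AND
    (intensity >= intensity_threshold)``.  The adaptive edge threshold
    scales with the image's own RMS gradient so the same ``edge_k`` works
    across exposure levels; closing (disk of ``closing_radius`` px) seals
    small contour gaps before hole filling.  An empty mask is a legal
    result (e.g. a constant image has no edges).
    """
    red = np.asarray(red_channel)
    if red.ndim != 2:
        raise ValueError("expected a single-channel image")
    redf = red.astype(np.float64)
    if np.issubdtype(red.dtype, np.integer):
        redf = redf / np.iinfo(red.dtype).max

    grad = sobel(redf)
    rms = float(np.sqrt(np.mean(grad**2)))
    edge_thr = edge_k * rms
    edges = grad > edge_thr
    if closing_radius > 0:
        edges = closing(edges, disk(closing_radius))
    filled = binary_fill_holes(edges)

    thr = intensity_threshold(
        red, fraction=threshold_fraction, top_percent=top_percent
    )
    bright = np.asarray(red, dtype=np.float64) >= thr if thr > 0 else np.zeros_like(filled)
    mask = filled & bright
    return NuclearMask(
        mask=mask,
        intensity_threshold=thr,
        edge_threshold=edge_thr,
        params={
            "edge_k": edge_k,
            "closing_radius": closing_radius,
            "threshold_fraction": threshold_fraction,
            "top_percent": top_percent,
            "rms_gradient": rms,
            "all_zero_input": bool(thr == 0.0),
        },
    )


def nc_small_patches(
    mask: NuclearMask | np.ndarray, patch_px: int = DEFAULT_PATCH_PX
) -> SmallPatchGrid:
    """Score N/C on a non-overlapping patch tiling anchored at (0, 0).

    N/C of a patch is the number of white (nucleus) pixels divided by the
    number of pixels actually inside the patch window, so partial edge
    patches are scored over their true area and flagged.
    """
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    m = mask.mask if isinstance(mask, NuclearMask) else np.asarray(mask, dtype=bool)
    h, w = m.shape
    rows = -(-h // patch_px)
    cols = -(-w // patch_px)
    ridx = np.arange(0, h, patch_px)
    cidx = np.arange(0, w, patch_px)
    whites = np.add.reduceat(
        np.add.reduceat(m.astype(np.int64), ridx, axis=0), cidx, axis=1
    )
    heights = np.minimum(ridx + patch_px, h) - ridx
    widths = np.minimum(cidx + patch_px, w) - cidx
    counts = np.outer(heights, widths).astype(np.int64)
    partial = np.zeros((rows, cols), dtype=bool)
    partial[heights < patch_px, :] = True
    partial[:, widths < patch_px] = True
    return SmallPatchGrid(
        patch_px=patch_px,
        nc=whites / counts,
        whites=whites,
        counts=counts,
        partial=partial,
    )


def merge_large_patches(
    grid: SmallPatchGrid,
    block: int = DEFAULT_BLOCK,
    zero_limit: int = DEFAULT_ZERO_LIMIT,
) -> pd.DataFrame:
    """Merge ``block x block`` small patches into large patches.

    The large-patch N/C is the arithmetic mean over all constituent small
    N/Cs, zeros included.  A full block is kept iff its count of cell-free
    small patches (N/C == 0) does not exceed ``zero_limit`` — with the
    defaults, a block with exactly 32 zeros is kept and one with 33 is
    excluded.  Edge blocks with fewer than ``block**2`` small patches are
    kept only if they contain at least half a block's worth of small patches
    and satisfy the zero rule proportionally.

    Returns a DataFrame with columns ``row, col, nc, n_small, n_zero,
    kept, partial``.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    nrows, ncols = grid.shape
    full = block * block
    records = []
    for br in range(-(-nrows // block)):
        for bc in range(-(-ncols // block)):
            sub = grid.nc[
                br * block : (br + 1) * block, bc * block : (bc + 1) * block
            ]
            n_small = sub.size
            n_zero = int((sub == 0.0).sum())
            mean_nc = float(sub.mean())
            if n_small == full:
                kept = n_zero <= zero_limit
            else:
                kept = (
                    n_small >= full / 2
                    and n_zero <= n_small * zero_limit / full
                )
            records.append(
                {
                    "row": br,
                    "col": bc,
                    "nc": mean_nc,
                    "n_small": n_small,
                    "n_zero": n_zero,
                    "kept": bool(kept),
                    "partial": n_small < full,
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["row", "col", "nc", "n_small", "n_zero", "kept", "partial"]
    )


def label_patches(
    table: pd.DataFrame,
    label_map: np.ndarray,
    label_codes: dict[str, int],
    patch_px: int = DEFAULT_PATCH_PX,
    block: int = DEFAULT_BLOCK,
) -> pd.DataFrame:
    """Assign each large patch the majority tissue class of its footprint.

    ``label_map`` is a raster of integer codes aligned to the mosaic, code 0
    meaning unlabeled.  Ties are broken toward the class that is rarer over
    the whole map (recorded in a ``tie`` column); patches whose footprint is
    entirely unlabeled get the label ``"unknown"``.
    """
    lm = np.asarray(label_map)
    code_to_name = {v: k for k, v in label_codes.items()}
    global_counts = np.bincount(lm.ravel(), minlength=max(label_codes.values()) + 1)
    side = patch_px * block
    labels, ties = [], []
    for rec in table.itertuples():
        y0, x0 = rec.row * side, rec.col * side
        foot = lm[y0 : y0 + side, x0 : x0 + side]
        counts = np.bincount(foot.ravel(), minlength=len(global_counts))
        counts[0] = 0  # unlabeled pixels never vote
        if counts.sum() == 0:
            labels.append("unknown")
            ties.append(False)
            continue
        best = counts.max()
        winners = np.nonzero(counts == best)[0]
        if len(winners) > 1:
            # toward the rarer class over the whole map
            winners = winners[np.argsort(global_counts[winners], kind="stable")]
            ties.append(True)
        else:
            ties.append(False)
        labels.append(code_to_name.get(int(winners[0]), "unknown"))
    out = table.copy()
    out["tissue_label"] = labels
    out["tie"] = ties
    return out
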