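"""Mosaic assembly from overlapping stage tiles.

The microscope acquires one RGB field of view per XY stage position with a
known nominal overlap between neighbours.  Stitching proceeds in three steps:

1. :func:`pairwise_offset` refines the nominal translation between each pair
   of overlapping tiles by maximising the Pearson correlation of the overlap
   region over a small integer search window (with optional sub-pixel
   refinement by a quadratic fit around the peak).
2. :func:`global_placement` reconciles the redundant pairwise links into one
   position per tile by weighted least squares, dropping low-correlation
   links in favour of the nominal stage offsets.
3. :func:`blend` composites the placed tiles onto a canvas with linear
   feather weights.

The registration model is translation-only: the stage is a calibrated XY
translator, so rotation and scale are fixed by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Tile",
    "PairLink",
    "Placement",
    "pairwise_offset",
    "global_placement",
    "blend",
    "tile_lightness",
]

#: Minimum overlap (px, each axis) required for pairwise registration.
MIN_OVERLAP_PX = 16

#: Links with correlation below this are replaced by the nominal offset.
DEFAULT_SCORE_THRESHOLD = 0.3

#: Correlation is scored on at most this many pixels per side of the
#: overlap (centred crop): plenty of signal at a fraction of the cost.
SCORE_WINDOW_PX = 192


@dataclass
class Tile:
    """One raw field of view with its grid index and nominal stage offset.

    ``nominal_offset_px`` is ``(dx, dy)`` from the mosaic origin, x = column
    direction, y = row direction, in pixels.
    """

    image: np.ndarray
    grid_row: int
    grid_col: int
    nominal_offset_px: tuple[float, float]

    @property
    def shape_px(self) -> tuple[int, int]:
        """(height, width) of the tile raster."""
        return self.image.shape[0], self.image.shape[1]


@dataclass
class PairLink:
    """Refined translation between two tiles plus its correlation score."""

    index_a: int
    index_b: int
    offset_px: tuple[float, float]  # refined (dx, dy): position_b - position_a
    nominal_px: tuple[float, float]
    score: float
    flagged: bool = False  # True when the overlap was constant / degenerate


@dataclass
class Placement:
    """Per-tile refined offsets plus the link table that produced them."""

    offsets_px: list[tuple[float, float]]
    links: list[PairLink] = field(default_factory=list)
    dropped_links: int = 0

    def rounded(self) -> list[tuple[int, int]]:
        """Integer offsets for resampling-free compositing."""
        return [(int(round(x)), int(round(y))) for x, y in self.offsets_px]


def tile_lightness(image: np.ndarray) -> np.ndarray:
    """Lightness (HSV value = per-pixel channel maximum) as float in [0, 1].

    Registration runs on lightness: the red/green fluorescence split carries
    no additional translation signal.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        v = img.max(axis=2)
    else:
        v = img
    v = v.astype(np.float64)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        v = v / np.iinfo(np.asarray(image).dtype).max
    return v


def _overlap_slices(
    shape_a: tuple[int, int], shape_b: tuple[int, int], dx: int, dy: int
) -> tuple[tuple[slice, slice], tuple[slice, slice]] | None:
    """Index slices of the overlap of two rasters when b sits at (dx, dy)
    relative to a. Returns ``None`` if they do not overlap."""
    ha, wa = shape_a
    hb, wb = shape_b
    x0, x1 = max(0, dx), min(wa, dx + wb)
    y0, y1 = max(0, dy), min(ha, dy + hb)
    if x1 <= x0 or y1 <= y0:
        return None
    sa = (slice(y0, y1), slice(x0, x1))
    sb = (slice(y0 - dy, y1 - dy), slice(x0 - dx, x1 - dx))
    return sa, sb


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u.ravel() - u.mean()
    v = v.ravel() - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    if denom == 0.0:
        return 0.0
    return float(np.clip((u @ v) / denom, -1.0, 1.0))


def _quadratic_peak(scores: np.ndarray, idx: int) -> float:
    """Sub-pixel offset of a 1-D correlation peak by parabola fit."""
    if idx <= 0 or idx >= len(scores) - 1:
        return 0.0
    c_m, c_0, c_p = scores[idx - 1], scores[idx], scores[idx + 1]
    denom = c_m - 2.0 * c_0 + c_p
    if denom == 0.0:
        return 0.0
    delta = 0.5 * (c_m - c_p) / denom
    return float(np.clip(delta, -0.5, 0.5))


def pairwise_offset(
    a: Tile,
    b: Tile,
    nominal: tuple[float, float] | None = None,
    search_radius_px: int = 8,
    subpixel: bool = False,
) -> tuple[tuple[float, float], float, bool]:
    """Refine the translation of tile ``b`` relative to tile ``a``.

    Scans integer shifts within ``search_radius_px`` of the nominal offset
    and scores each candidate by the Pearson correlation of the lightness
    channels over the implied overlap.

    Returns ``((dx, dy), score, flagged)``.  ``flagged`` is True when the
    overlap is constant on either side, in which case the nominal offset is
    returned with score 0.

    Raises
    ------
    ValueError
        If the tiles overlap by fewer than ``MIN_OVERLAP_PX`` pixels in
        either dimension under the nominal offset.
    """
    if nominal is None:
        nominal = (
            b.nominal_offset_px[0] - a.nominal_offset_px[0],
            b.nominal_offset_px[1] - a.nominal_offset_px[1],
        )
    ndx, ndy = int(round(nominal[0])), int(round(nominal[1]))
    va = tile_lightness(a.image)
    vb = tile_lightness(b.image)

    sl = _overlap_slices(va.shape, vb.shape, ndx, ndy)
    if sl is None:
        raise ValueError("tiles do not overlap under the nominal offset")
    oh = sl[0][0].stop - sl[0][0].start
    ow = sl[0][1].stop - sl[0][1].start
    if oh < MIN_OVERLAP_PX or ow < MIN_OVERLAP_PX:
        raise ValueError(
            f"overlap {ow}x{oh} px under nominal offset is below the "
            f"{MIN_OVERLAP_PX} px minimum required for registration"
        )
    if np.ptp(va[sl[0]]) == 0.0 or np.ptp(vb[sl[1]]) == 0.0:
        return (float(ndx), float(ndy)), 0.0, True

    r = int(search_radius_px)
    size = 2 * r + 1
    scores = np.full((size, size), -np.inf)
    for iy in range(size):
        for ix in range(size):
            dx, dy = ndx + ix - r, ndy + iy - r
            sl_c = _overlap_slices(va.shape, vb.shape, dx, dy)
            if sl_c is None:
                continue
            pa, pb = va[sl_c[0]], vb[sl_c[1]]
            if pa.shape[0] < MIN_OVERLAP_PX // 2 or pa.shape[1] < MIN_OVERLAP_PX // 2:
                continue
            if pa.shape[0] > SCORE_WINDOW_PX or pa.shape[1] > SCORE_WINDOW_PX:
                y0 = max(0, (pa.shape[0] - SCORE_WINDOW_PX) // 2)
                x0 = max(0, (pa.shape[1] - SCORE_WINDOW_PX) // 2)
                pa = pa[y0 : y0 + SCORE_WINDOW_PX, x0 : x0 + SCORE_WINDOW_PX]
                pb = pb[y0 : y0 + SCORE_WINDOW_PX, x0 : x0 + SCORE_WINDOW_PX]
            scores[iy, ix] = _pearson(pa, pb)

    iy, ix = np.unravel_index(int(np.argmax(scores)), scores.shape)
    best = float(scores[iy, ix])
    dx = float(ndx + ix - r)
    dy = float(ndy + iy - r)
    if subpixel:
        finite_row = np.where(np.isfinite(scores[iy]), scores[iy], best - 1.0)
        finite_col = np.where(np.isfinite(scores[:, ix]), scores[:, ix], best - 1.0)
        dx += _quadratic_peak(finite_row, ix)
        dy += _quadratic_peak(finite_col, iy)
    return (dx, dy), best, False


def global_placement(
    n_tiles: int,
    links: list[PairLink],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> Placement:
    """Solve tile positions from redundant pairwise links by least squares.

    Each link contributes the equation ``p_b - p_a = offset`` weighted by its
    correlation score.  Links scoring below ``score_threshold`` (or flagged
    degenerate) are dropped and replaced by their nominal offsets at low
    weight.  The first tile is pinned at the origin.  If the link graph
    leaves some tiles disconnected from tile 0, those tiles fall back to
    nominal offsets and a warning is emitted.
    """
    if n_tiles < 1:
        raise ValueError("need at least one tile")
    if n_tiles == 1:
        return Placement(offsets_px=[(0.0, 0.0)], links=list(links))

    rows: list[tuple[int, int, float, float, float]] = []  # a, b, dx, dy, w
    dropped = 0
    adj = np.zeros((n_tiles, n_tiles), dtype=bool)
    for lk in links:
        adj[lk.index_a, lk.index_b] = adj[lk.index_b, lk.index_a] = True
        if lk.flagged or lk.score < score_threshold:
            dropped += 1
            rows.append((lk.index_a, lk.index_b, *lk.nominal_px, 0.05))
        else:
            rows.append((lk.index_a, lk.index_b, *lk.offset_px, max(lk.score, 0.05)))

    n_comp, comp = connected_components(adj, directed=False)
    if n_comp > 1:
        warnings.warn(
            "tile link graph is disconnected; disconnected tiles fall back "
            "to nominal offsets",
            stacklevel=2,
        )

    # Weighted least squares per axis; anchor p_0 = 0 with a strong equation.
    m = len(rows) + 1
    amat = np.zeros((m, n_tiles))
    bx = np.zeros(m)
    by = np.zeros(m)
    for k, (ia, ib, dx, dy, w) in enumerate(rows):
        amat[k, ia] = -w
        amat[k, ib] = w
        bx[k] = w * dx
        by[k] = w * dy
    amat[-1, 0] = 1000.0

    px, *_ = np.linalg.lstsq(amat, bx, rcond=None)
    py, *_ = np.linalg.lstsq(amat, by, rcond=None)
    px -= px[0]
    py -= py[0]
    return Placement(
        offsets_px=[(float(px[i]), float(py[i])) for i in range(n_tiles)],
        links=list(links),
        dropped_links=dropped,
    )


def blend(tiles: list[Tile], placement: Placement) -> np.ndarray:
    """Composite placed tiles with linear feather blending.

    Offsets are rounded to integers before compositing so no tile is ever
    resampled (sub-pixel interpolation would blur the nuclei the downstream
    segmentation depends on).  Feather weights ramp linearly from the tile
    border inward, so in overlaps the tile whose border is farther away
    dominates; where all contributing tiles agree the output equals their
    common value exactly after re-quantisation.  Uncovered canvas is 0.
    """
    if len(tiles) != len(placement.offsets_px):
        raise ValueError("one offset per tile required")
    offsets = placement.rounded()
    # normalise so the canvas origin is the minimum placed corner
    min_x = min(o[0] for o in offsets)
    min_y = min(o[1] for o in offsets)
    offsets = [(x - min_x, y - min_y) for x, y in offsets]
    max_x = max(o[0] + t.image.shape[1] for o, t in zip(offsets, tiles))
    max_y = max(o[1] + t.image.shape[0] for o, t in zip(offsets, tiles))

    first = tiles[0].image
    n_ch = first.shape[2] if first.ndim == 3 else 1
    acc = np.zeros((max_y, max_x, n_ch), dtype=np.float64)
    wsum = np.zeros((max_y, max_x), dtype=np.float64)
    for tile, (x, y) in zip(tiles, offsets):
        img = tile.image
        h, w = img.shape[0], img.shape[1]
        # distance-to-border feather, >= 1 so border pixels still contribute
        yy = np.minimum(np.arange(h) + 1, h - np.arange(h))
        xx = np.minimum(np.arange(w) + 1, w - np.arange(w))
        weight = np.minimum.outer(yy, xx).astype(np.float64)
        chans = img.astype(np.float64).reshape(h, w, n_ch)
        acc[y : y + h, x : x + w] += weight[:, :, None] * chans
        wsum[y : y + h, x : x + w] += weight

    out = np.zeros_like(acc)
    covered = wsum > 0
    out[covered] = acc[covered] / wsum[covered][:, None]
    if np.issubdtype(first.dtype, np.integer):
        info = np.iinfo(first.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(first.dtype)
    else:
        out = out.astype(first.dtype)
    if first.ndim == 2:
        out = out[:, :, 0]
    return out
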