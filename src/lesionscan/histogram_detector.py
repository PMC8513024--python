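"""Lesion detection from the low-intensity tail of local skin histograms.

Small patches of healthy skin have near-Gaussian per-channel intensity
histograms. A pigmented lesion occupying a minority of a patch adds a tail on
the low-brightness side, most visibly in the green and blue channels. The
detector tiles the skin region, models each tile's healthy-skin distribution
by its histogram mode, estimates the distribution half-width as
``max_intensity - mode`` (right edge minus peak: the right side is lesion
free), and flags pixels darker than ``mode - width = 2*mode - max`` in *both*
the green and blue channels. Tile masks are OR-combined over the overlapping
grid, connected components labelled, and speckle below a minimum equivalent
diameter dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import RgbImage, as_binary_mask, connected_components, mm_to_px

__all__ = [
    "ChannelHistogram",
    "TileGrid",
    "HistogramParams",
    "smooth_histogram",
    "channel_threshold",
    "tile_lesion_mask",
    "detect_histogram",
]


@dataclass(frozen=True)
class HistogramParams:
    tile_size: int = 128
    overlap: int = 64  # 50% default: every interior pixel is seen by >=4 tiles
    smooth_window: int = 5
    right_edge_percentile: float = 99.9
    min_diameter_mm: float = 1.0
    min_skin_fraction: float = 0.25  # tiles with less skin are skipped
    combine: str = "or"  # "or" (default) or "vote" with min_votes
    min_votes: int = 2


@dataclass(frozen=True)
class ChannelHistogram:
    """256-bin histogram of one channel over one tile's skin pixels."""

    counts: np.ndarray
    smoothed: np.ndarray = field(repr=False)
    mode: int
    max_intensity: int

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        smooth_window: int = 5,
        right_edge_percentile: float = 100.0,
    ) -> "ChannelHistogram":
        """Build from raw intensities.

        ``mode`` is the peak of the smoothed histogram (ties broken toward
        the lowest intensity: a smaller estimated width flags fewer pixels).
        ``max_intensity`` is the highest populated intensity — by default the
        literal right edge; a percentile slightly below 100 makes the edge
        robust to single-pixel outliers.
        """
        if values.size == 0:
            raise ValueError("no pixels to histogram")
        counts = np.bincount(np.asarray(values, dtype=np.uint8).ravel(), minlength=256)
        smoothed = smooth_histogram(counts.astype(np.float64), smooth_window)
        mode = int(np.argmax(smoothed))
        cdf = np.cumsum(smoothed)
        if cdf[-1] <= 0:
            raise ValueError("all-zero histogram")
        target = cdf[-1] * right_edge_percentile / 100.0
        max_intensity = int(np.searchsorted(cdf, target))
        max_intensity = max(max_intensity, mode)
        return cls(counts=counts, smoothed=smoothed, mode=mode, max_intensity=max_intensity)


def smooth_histogram(counts: np.ndarray, window: int) -> np.ndarray:
    """Moving-average smoothing with reflective boundaries.

    The window must be odd so the filter is centred and mass is preserved up
    to the boundary reflection.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    counts = np.asarray(counts, dtype=np.float64)
    if window == 1:
        return counts.copy()
    half = window // 2
    padded = np.pad(counts, half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def channel_threshold(hist: ChannelHistogram) -> int:
    """Tail threshold ``th = mode - (max - mode) = 2*mode - max``, clamped to >= 0.

    ``max - mode`` estimates the healthy-skin distribution's half width from
    the lesion-free right side of the histogram; pixels darker than the mode
    by more than that width belong to the tail. A constant tile degenerates
    to ``th = mode`` (width 0), which flags nothing under the strict
    inequality used downstream.
    """
    if hist.counts.sum() == 0:
        raise ValueError("all-zero histogram")
    return max(0, 2 * hist.mode - hist.max_intensity)


def tile_lesion_mask(
    tile_g: np.ndarray,
    tile_b: np.ndarray,
    th_g: int,
    th_b: int,
    skin: np.ndarray | None = None,
) -> np.ndarray:
    """Per-tile lesion mask: strictly below threshold in green AND blue.

    Non-skin pixels (``skin == 0``) are forced to 0.
    """
    tile_g = np.asarray(tile_g)
    tile_b = np.asarray(tile_b)
    if tile_g.shape != tile_b.shape:
        raise ValueError("green/blue tiles must share a shape")
    mask = (tile_g < th_g) & (tile_b < th_b)
    if skin is not None:
        mask &= as_binary_mask(skin, tile_g.shape)
    return mask


@dataclass(frozen=True)
class TileGrid:
    """Overlapping square tiles covering an image."""

    tile_size: int
    overlap: int
    rects: tuple[tuple[int, int, int, int], ...]  # (r0, c0, height, width)

    @classmethod
    def cover(cls, image_shape: tuple[int, int], tile_size: int, overlap: int) -> "TileGrid":
        if not 0 <= overlap < tile_size:
            raise ValueError("need 0 <= overlap < tile_size")
        stride = tile_size - overlap
        h, w = image_shape

        def starts(extent: int) -> list[int]:
            if extent <= tile_size:
                return [0]
            s = list(range(0, extent - tile_size, stride))
            s.append(extent - tile_size)  # final tile shifted inward to fit
            return s

        rects = tuple(
            (r0, c0, min(tile_size, h), min(tile_size, w))
            for r0 in starts(h)
            for c0 in starts(w)
        )
        return cls(tile_size=tile_size, overlap=overlap, rects=rects)


def detect_histogram(
    image: RgbImage,
    skin: np.ndarray,
    params: HistogramParams | None = None,
) -> np.ndarray:
    """Full-image histogram-tail detection; returns a label mask.

    For each tile of the overlapping grid, green and blue histograms are
    computed over skin pixels only, smoothed, thresholded, and the per-tile
    masks combined across the grid (logical OR by default). Components
    smaller than the configured minimum equivalent diameter are dropped.
    """
    params = params or HistogramParams()
    skin = as_binary_mask(skin, image.shape)
    votes = np.zeros(image.shape, dtype=np.int16)
    if skin.any():
        grid = TileGrid.cover(image.shape, params.tile_size, params.overlap)
        g_full = image.channel(1)
        b_full = image.channel(2)
        for r0, c0, th_, tw_ in grid.rects:
            sl = (slice(r0, r0 + th_), slice(c0, c0 + tw_))
            tile_skin = skin[sl]
            n_skin = int(tile_skin.sum())
            if n_skin < params.min_skin_fraction * tile_skin.size:
                continue
            tile_g = g_full[sl]
            tile_b = b_full[sl]
            hist_g = ChannelHistogram.from_values(
                tile_g[tile_skin], params.smooth_window, params.right_edge_percentile
            )
            hist_b = ChannelHistogram.from_values(
                tile_b[tile_skin], params.smooth_window, params.right_edge_percentile
            )
            tile_mask = tile_lesion_mask(
                tile_g, tile_b, channel_threshold(hist_g), channel_threshold(hist_b), tile_skin
            )
            votes[sl] += tile_mask

    if params.combine == "or":
        mask = votes >= 1
    elif params.combine == "vote":
        mask = votes >= params.min_votes
    else:
        raise ValueError(f"unknown combine mode {params.combine!r}")

    labels = connected_components(mask, connectivity=8)
    return _drop_small(labels, params.min_diameter_mm, image.mm_per_px)


def _drop_small(labels: np.ndarray, min_diameter_mm: float, mm_per_px: float) -> np.ndarray:
    """Remove components whose equivalent diameter is below the minimum."""
    k = int(labels.max(initial=0))
    if k == 0:
        return labels
    min_area_px = np.pi * (min_diameter_mm / 2.0) ** 2 / mm_per_px**2
    areas = np.bincount(labels.ravel(), minlength=k + 1)
    keep = areas >= min_area_px
    keep[0] = False
    remap = np.zeros(k + 1, dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return remap[labels]
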