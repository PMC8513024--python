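"""Frame tiling, NMS and in-box Otsu segmentation around an external box detector.

A deep detector operating on fixed-size inputs sees a whole-body photograph
as overlapping square frames; boxes found in different frames duplicate where
the frames overlap and are reconciled with non-maximum suppression. Each
surviving box is then segmented: green-channel crop, 5x5 median filter, Otsu
threshold, darker class, largest connected component.

The detector itself is pluggable: ``load_boxes`` consumes boxes produced by
any external model, and ``stub_detector`` is a deterministic dark-blob
proposer so the three-way fusion can be exercised without trained weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    BoundingBox,
    LesionRecord,
    RgbImage,
    as_binary_mask,
    connected_components,
    labels_from_records,
)

__all__ = [
    "FramePlan",
    "plan_frames",
    "nms",
    "otsu_threshold",
    "segment_box",
    "stub_detector",
    "StubParams",
    "segment_boxes",
]


@dataclass(frozen=True)
class FramePlan:
    """Square frames covering an image with a fixed overlap."""

    frame_size_px: int
    overlap_px: int
    offsets: tuple[tuple[int, int], ...]  # (row, col) top-left corners
    pad: tuple[int, int] = (0, 0)  # (rows, cols) of padding if image < frame


def plan_frames(
    image_shape: tuple[int, int], frame_size: int = 416, overlap: int = 118
) -> FramePlan:
    """Plan overlapping frames with stride ``frame_size - overlap``.

    The final frame in each direction is shifted inward so no frame exceeds
    the image; an image smaller than one frame yields a single frame with
    the padding deficit recorded.
    """
    if not frame_size > overlap >= 0:
        raise ValueError("need frame_size > overlap >= 0")
    h, w = image_shape
    stride = frame_size - overlap

    def starts(extent: int) -> list[int]:
        if extent <= frame_size:
            return [0]
        s = list(range(0, extent - frame_size, stride))
        s.append(extent - frame_size)
        return s

    offsets = tuple((r, c) for r in starts(h) for c in starts(w))
    pad = (max(0, frame_size - h), max(0, frame_size - w))
    return FramePlan(frame_size_px=frame_size, overlap_px=overlap, offsets=offsets, pad=pad)


def nms(boxes: list[BoundingBox], iou_threshold: float = 0.5) -> list[BoundingBox]:
    """Greedy non-maximum suppression by descending confidence.

    Ties in confidence are broken by (x0, y0) so the result is independent
    of input order.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    ordered = sorted(boxes, key=lambda b: (-b.confidence, b.x0, b.y0, b.width, b.height))
    kept: list[BoundingBox] = []
    for box in ordered:
        if all(box.iou(k) <= iou_threshold for k in kept):
            kept.append(box)
    return kept


def otsu_threshold(values: np.ndarray) -> int:
    """Otsu's threshold on 8-bit values: maximal between-class variance.

    Returns t splitting classes ``[0..t]`` and ``[t+1..255]``; ties resolve
    to the smallest t. Raises on constant input, where the split is
    undefined.
    """
    hist = np.bincount(np.asarray(values, dtype=np.uint8).ravel(), minlength=256).astype(
        np.float64
    )
    total = hist.sum()
    if total == 0 or np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined for constant input")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    mu_total = m0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mean0 - mean1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b[:-1]))


def segment_box(
    image: RgbImage,
    box: BoundingBox,
    median_kernel_px: int = 5,
    dark_lesion: bool = True,
) -> tuple[np.ndarray, bool]:
    """Segment the lesion inside a box: median filter, Otsu, largest dark blob.

    Returns the boolean crop (shape = box extent) and a degenerate flag,
    true when the crop is constant and Otsu is undefined (empty mask).
    Lesions are darker than skin, so the darker Otsu class is kept by
    default; ``dark_lesion=False`` flips the polarity.
    """
    box = box.clip(image.shape)
    crop = image.green[box.slices()]
    filtered = ndimage.median_filter(crop, size=median_kernel_px)
    try:
        t = otsu_threshold(filtered)
    except ValueError:
        return np.zeros(crop.shape, dtype=bool), True
    mask = filtered <= t if dark_lesion else filtered > t
    labels = connected_components(mask, connectivity=8)
    if labels.max(initial=0) == 0:
        return np.zeros(crop.shape, dtype=bool), True
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    return labels == int(np.argmax(areas)), False


@dataclass(frozen=True)
class StubParams:
    """Dark-blob proposer settings (stands in for a trained box detector)."""

    k_sigma: float = 3.5
    min_diameter_mm: float = 1.0
    frame_size: int = 416
    overlap: int = 118
    box_margin_px: int = 2


def stub_detector(
    image: RgbImage, skin: np.ndarray, params: StubParams | None = None
) -> list[BoundingBox]:
    """Deterministic dark-blob box proposer.

    Within each planned frame, skin pixels of the green channel are modelled
    robustly (median and MAD-based sigma); pixels darker than
    ``median - k_sigma * sigma`` are flagged. Flagged pixels are OR-combined
    across frames, small components dropped, and each remaining component
    boxed with a small margin; confidence is the component's darkness
    contrast relative to the frame median, clipped to [0, 1].
    """
    params = params or StubParams()
    skin = as_binary_mask(skin, image.shape)
    green = image.green
    flagged = np.zeros(image.shape, dtype=bool)
    contrast_ref = np.zeros(image.shape, dtype=np.float64)
    plan = plan_frames(image.shape, params.frame_size, params.overlap)
    for r0, c0 in plan.offsets:
        sl = (
            slice(r0, min(r0 + plan.frame_size_px, image.shape[0])),
            slice(c0, min(c0 + plan.frame_size_px, image.shape[1])),
        )
        frame_skin = skin[sl]
        if not frame_skin.any():
            continue
        vals = green[sl][frame_skin].astype(np.float64)
        med = np.median(vals)
        sigma = 1.4826 * np.median(np.abs(vals - med))
        if sigma == 0:
            continue
        thr = med - params.k_sigma * sigma
        frame_flag = (green[sl] < thr) & frame_skin
        flagged[sl] |= frame_flag
        np.maximum(contrast_ref[sl], med, out=contrast_ref[sl])

    labels = connected_components(flagged, connectivity=8)
    k = int(labels.max(initial=0))
    min_area_px = np.pi * (params.min_diameter_mm / 2.0) ** 2 / image.mm_per_px**2
    boxes: list[BoundingBox] = []
    for slc, lab in zip(ndimage.find_objects(labels), range(1, k + 1)):
        comp = labels[slc] == lab
        if comp.sum() < min_area_px:
            continue
        m = params.box_margin_px
        r0 = max(0, slc[0].start - m)
        c0 = max(0, slc[1].start - m)
        r1 = min(image.shape[0], slc[0].stop + m)
        c1 = min(image.shape[1], slc[1].stop + m)
        med = contrast_ref[slc][comp].max()
        comp_mean = green[slc][comp].mean()
        conf = float(np.clip((med - comp_mean) / max(med, 1.0), 0.0, 1.0))
        boxes.append(BoundingBox(x0=c0, y0=r0, width=c1 - c0, height=r1 - r0, confidence=conf))
    return boxes


def segment_boxes(
    image: RgbImage,
    boxes: list[BoundingBox],
    skin: np.ndarray | None = None,
    iou_threshold: float = 0.5,
    median_kernel_px: int = 5,
) -> tuple[np.ndarray, list[LesionRecord]]:
    """NMS then per-box Otsu segmentation; returns labels and records."""
    kept = nms(boxes, iou_threshold)
    records: list[LesionRecord] = []
    for box in kept:
        mask_crop, degenerate = segment_box(image, box, median_kernel_px)
        if skin is not None:
            mask_crop = mask_crop & as_binary_mask(skin, image.shape)[box.clip(image.shape).slices()]
        if degenerate or not mask_crop.any():
            continue
        rows, cols = np.nonzero(mask_crop)
        clipped = box.clip(image.shape)
        records.append(
            LesionRecord(
                id=len(records) + 1,
                centroid=(
                    float(rows.mean() + clipped.y0),
                    float(cols.mean() + clipped.x0),
                ),
                mask_crop=mask_crop,
                offset=(clipped.y0, clipped.x0),
                sources=frozenset(["boxes"]),
                score=box.confidence,
            )
        )
    labels = labels_from_records(records, image.shape)
    return labels, records
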