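"""Shared domain types, coordinate conventions and calibration.

Conventions used throughout the package:

* rasters are numpy arrays indexed ``(row, col)``, 0-based, top-left origin;
* an RGB image is ``(H, W, 3)`` with intensities in ``[0, 255]``;
* a binary mask is boolean with the shape of its source image;
* a label mask is an integer raster with background 0 and lesion labels
  contiguous ``1..K``, assigned in raster-scan order of each region's first
  pixel;
* physical sizes are always ``pixels * mm_per_px`` — the pixel pitch is an
  explicit, required calibration input, never guessed from metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "RgbImage",
    "BoundingBox",
    "LesionRecord",
    "to_ycbcr",
    "connected_components",
    "as_binary_mask",
    "validate_label_mask",
    "mm_to_px",
    "read_image",
    "write_image",
    "read_label_mask",
    "write_label_mask",
    "load_boxes",
    "save_boxes",
]


@dataclass(frozen=True)
class RgbImage:
    """An RGB photograph with its pixel-to-millimetre calibration.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` array, intensities in ``[0, 255]`` (stored as uint8).
    mm_per_px
        Physical side length of one pixel in millimetres; strictly positive.
    """

    pixels: np.ndarray
    mm_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"expected (H, W, 3) pixel array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.mm_per_px > 0:
            raise ValueError(f"mm_per_px must be positive, got {self.mm_per_px}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape as ``(H, W)``."""
        return self.pixels.shape[:2]

    def channel(self, index: int) -> np.ndarray:
        """A single colour channel as uint8 (0=R, 1=G, 2=B)."""
        return self.pixels[:, :, index]

    @property
    def green(self) -> np.ndarray:
        return self.channel(1)

    def with_pixels(self, pixels: np.ndarray) -> "RgbImage":
        """Same calibration, new pixel data."""
        return replace(self, pixels=pixels)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel box: top-left (x0, y0), inclusive extents.

    ``x0`` is the column and ``y0`` the row of the top-left pixel; ``width``
    and ``height`` count pixels, so the box covers rows
    ``y0 .. y0 + height - 1`` and columns ``x0 .. x0 + width - 1``.
    """

    x0: int
    y0: int
    width: int
    height: int
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("box width and height must be >= 1")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def area(self) -> int:
        return self.width * self.height

    def clip(self, image_shape: tuple[int, int]) -> "BoundingBox":
        """Clip the box to image bounds; raises if nothing remains."""
        h, w = image_shape
        x0 = max(0, self.x0)
        y0 = max(0, self.y0)
        x1 = min(w, self.x0 + self.width)
        y1 = min(h, self.y0 + self.height)
        if x1 <= x0 or y1 <= y0:
            raise ValueError(f"box {self} lies entirely outside image {image_shape}")
        return BoundingBox(x0, y0, x1 - x0, y1 - y0, self.confidence)

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.y0, self.y0 + self.height),
            slice(self.x0, self.x0 + self.width),
        )

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union with another box."""
        ix0 = max(self.x0, other.x0)
        iy0 = max(self.y0, other.y0)
        ix1 = min(self.x0 + self.width, other.x0 + other.width)
        iy1 = min(self.y0 + self.height, other.y0 + other.height)
        inter = max(0, ix1 - ix0) * max(0, iy1 - iy0)
        if inter == 0:
            return 0.0
        return inter / (self.area + other.area - inter)


@dataclass
class LesionRecord:
    """One detected (or ground-truth) lesion.

    The mask is stored as a crop plus its top-left offset in the image frame
    so that records from images of any size stay lightweight.
    """

    id: int
    centroid: tuple[float, float]  # (row, col), image frame
    mask_crop: np.ndarray  # boolean crop
    offset: tuple[int, int]  # (row, col) of crop's top-left pixel
    sources: frozenset[str] = field(default_factory=frozenset)
    score: float = 1.0  # detector-specific confidence (e.g. NCC gamma)
    geometry: "object | None" = None  # morphometry.LesionGeometry, filled later
    degenerate: bool = False

    def full_mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Paste the crop back into a full-frame boolean mask."""
        out = np.zeros(image_shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.mask_crop.shape
        out[r0 : r0 + h, c0 : c0 + w] = self.mask_crop
        return out

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask_crop))


# ---------------------------------------------------------------------------
# raster validation helpers


def as_binary_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Coerce to a boolean mask, checking values are in {0, 1}."""
    arr = np.asarray(mask)
    if arr.dtype != bool:
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("binary mask values must be in {0, 1}")
        arr = arr.astype(bool)
    if shape is not None and arr.shape != tuple(shape):
        raise ValueError(f"mask shape {arr.shape} does not match expected {shape}")
    return arr


def validate_label_mask(labels: np.ndarray) -> np.ndarray:
    """Check a label raster has contiguous labels {0} ∪ {1..K} and return it."""
    arr = np.asarray(labels)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("label mask must be integer-typed")
    present = np.unique(arr)
    if present.size and present[0] < 0:
        raise ValueError("label mask must be non-negative")
    k = int(present.max(initial=0))
    if k > 0 and np.setdiff1d(np.arange(1, k + 1), present).size:
        raise ValueError("labels must be contiguous 1..K plus background 0")
    return arr


def mm_to_px(length_mm: float, mm_per_px: float) -> int:
    """Convert a physical length to a pixel count (nearest integer, min 1)."""
    return max(1, int(round(length_mm / mm_per_px)))


# ---------------------------------------------------------------------------
# operations


#: ITU-R BT.601 full-range luma/chroma weights.
_BT601 = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)


def to_ycbcr(image: RgbImage) -> np.ndarray:
    """Convert to YCbCr (BT.601 full-range), float ``(H, W, 3)``.

    Y lies in [0, 255]; Cb and Cr are offset by +128.
    """
    rgb = image.pixels.astype(np.float64)
    ycc = rgb @ _BT601.T
    ycc[:, :, 1:] += 128.0
    return ycc


def luma(image: RgbImage) -> np.ndarray:
    """BT.601 luma channel Y in [0, 255] as float."""
    return to_ycbcr(image)[:, :, 0]


def connected_components(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected regions 1..K in raster-scan order of first pixels.

    Parameters
    ----------
    mask
        Binary raster.
    connectivity
        4 (edge-adjacent) or 8 (edge- or corner-adjacent, the default: lesions
        are blob-like and 4-connectivity would split anti-aliased edges).
    """
    mask = as_binary_mask(mask)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    labels, k = ndimage.label(mask, structure=structure)
    if k == 0:
        return labels.astype(np.int32)
    # scipy already assigns labels in raster-scan order of first pixels, but
    # that is an implementation detail; relabel explicitly to guarantee it.
    flat_first = ndimage.labeled_comprehension(
        np.arange(labels.size).reshape(labels.shape),
        labels,
        np.arange(1, k + 1),
        np.min,
        int,
        0,
    )
    order = np.argsort(flat_first, kind="stable")
    remap = np.zeros(k + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, k + 1)
    return remap[labels]


def records_from_labels(
    labels: np.ndarray, source: str = "", scores: Sequence[float] | None = None
) -> list[LesionRecord]:
    """Split a label mask into per-lesion records with tight crops."""
    labels = validate_label_mask(labels)
    out: list[LesionRecord] = []
    objects = ndimage.find_objects(labels)
    for idx, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        crop = labels[slc] == idx
        rows, cols = np.nonzero(crop)
        centroid = (
            float(rows.mean() + slc[0].start),
            float(cols.mean() + slc[1].start),
        )
        out.append(
            LesionRecord(
                id=idx,
                centroid=centroid,
                mask_crop=crop,
                offset=(slc[0].start, slc[1].start),
                sources=frozenset([source]) if source else frozenset(),
                score=1.0 if scores is None else float(scores[idx - 1]),
            )
        )
    return out


def labels_from_records(
    records: Sequence[LesionRecord], image_shape: tuple[int, int]
) -> np.ndarray:
    """Rasterise records into a label mask, ids assigned in list order."""
    out = np.zeros(image_shape, dtype=np.int32)
    for i, rec in enumerate(records, start=1):
        r0, c0 = rec.offset
        h, w = rec.mask_crop.shape
        view = out[r0 : r0 + h, c0 : c0 + w]
        view[rec.mask_crop] = i
    return out


# ---------------------------------------------------------------------------
# persistence


def read_image(path: str | Path, mm_per_px: float) -> RgbImage:
    """Read a PNG/TIFF/JPEG photograph, attaching its calibration."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RgbImage(arr, mm_per_px)


def write_image(path: str | Path, image: RgbImage) -> None:
    iio.imwrite(path, image.pixels)


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read a label mask stored as 16-bit single-channel PNG."""
    arr = iio.imread(path)
    return validate_label_mask(arr.astype(np.int32))


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    labels = validate_label_mask(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 lesions cannot be stored as 16-bit PNG")
    iio.imwrite(path, labels.astype(np.uint16))


def load_boxes(path: str | Path, image_shape: tuple[int, int] | None = None) -> list[BoundingBox]:
    """Load bounding boxes from a JSON array of objects.

    Each entry carries ``x0, y0, width, height`` and an optional
    ``confidence`` (defaulted to 1.0). Boxes are clipped to ``image_shape``
    when given.
    """
    text = Path(path).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed boxes JSON at {path}, line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(raw, list):
        raise ValueError("boxes file must contain a JSON array")
    boxes = []
    for entry in raw:
        box = BoundingBox(
            x0=int(entry["x0"]),
            y0=int(entry["y0"]),
            width=int(entry["width"]),
            height=int(entry["height"]),
            confidence=float(entry.get("confidence", 1.0)),
        )
        if image_shape is not None:
            box = box.clip(image_shape)
        boxes.append(box)
    return boxes


def save_boxes(path: str | Path, boxes: Sequence[BoundingBox]) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "x0": b.x0,
                    "y0": b.y0,
                    "width": b.width,
                    "height": b.height,
                    "confidence": b.confidence,
                }
                for b in boxes
            ],
            indent=2,
        )
    )
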