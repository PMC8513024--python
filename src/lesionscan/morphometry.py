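"""Geometric descriptors of segmented lesions and comparison statistics.

The clinically relevant descriptors are the lesion's area, the diameter of
the equivalent circle (same area), the best-fit ellipse (major/minor axis and
the major-axis angle against the horizontal image axis), and the maximum
Feret (caliper) diameter. Segmentations are compared to reference outlines
by per-parameter relative error and by the Dice overlap coefficient,
stratified by reference lesion size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull

from .core import LesionRecord, as_binary_mask

__all__ = [
    "LesionGeometry",
    "measure",
    "relative_error",
    "dice",
    "angle_error_percent",
    "geometry_report",
    "record_overlap",
    "record_dice",
]

#: below this eccentricity the ellipse angle is meaningless; its error is
#: recorded as 0 by convention and flagged
ECCENTRICITY_FLOOR = 0.1


@dataclass(frozen=True)
class LesionGeometry:
    """Physical-unit geometry of one lesion mask."""

    area_mm2: float
    equivalent_diameter_mm: float
    ellipse_major_mm: float
    ellipse_minor_mm: float
    ellipse_angle_deg: float  # major axis vs. horizontal Ox, in [-90, 90)
    max_feret_mm: float
    eccentricity: float
    angle_defined: bool


def measure(mask: np.ndarray, mm_per_px: float) -> LesionGeometry:
    """Measure a lesion mask.

    Area is the pixel count scaled by ``mm_per_px**2``; the ellipse comes
    from the second central moments (each pixel treated as a unit square, so
    a single pixel has finite axes); the angle is measured from the +x
    (column) axis toward +y (rows, downward) and normalized to [-90, 90).
    The maximum Feret diameter is the largest distance between boundary
    pixel centres plus one pixel of extent, so a 1-pixel lesion has Feret
    diameter 1 px.
    """
    mask = as_binary_mask(mask)
    rows, cols = np.nonzero(mask)
    n = rows.size
    if n == 0:
        raise ValueError("cannot measure an empty mask")
    area_mm2 = n * mm_per_px**2
    eq_diam = 2.0 * np.sqrt(area_mm2 / np.pi)

    x = cols.astype(np.float64)
    y = rows.astype(np.float64)
    cxx = x.var() + 1.0 / 12.0
    cyy = y.var() + 1.0 / 12.0
    cxy = ((x - x.mean()) * (y - y.mean())).mean()
    common = np.sqrt(max((cxx - cyy) ** 2 + 4 * cxy**2, 0.0))
    l1 = (cxx + cyy + common) / 2.0
    l2 = (cxx + cyy - common) / 2.0
    major = 4.0 * np.sqrt(max(l1, 0.0)) * mm_per_px
    minor = 4.0 * np.sqrt(max(l2, 0.0)) * mm_per_px
    angle = np.degrees(0.5 * np.arctan2(2 * cxy, cxx - cyy))
    angle = ((angle + 90.0) % 180.0) - 90.0
    ecc = np.sqrt(1.0 - (l2 / l1)) if l1 > 0 else 0.0

    return LesionGeometry(
        area_mm2=float(area_mm2),
        equivalent_diameter_mm=float(eq_diam),
        ellipse_major_mm=float(major),
        ellipse_minor_mm=float(minor),
        ellipse_angle_deg=float(angle),
        max_feret_mm=float(_max_feret_px(mask) * mm_per_px),
        eccentricity=float(ecc),
        angle_defined=bool(ecc >= ECCENTRICITY_FLOOR),
    )


def _max_feret_px(mask: np.ndarray) -> float:
    """Max pairwise distance between boundary pixel centres + 1 px extent."""
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.column_stack(np.nonzero(boundary)).astype(np.float64)
    if len(pts) == 1:
        return 1.0
    if len(pts) > 16:
        try:
            hull = ConvexHull(pts)
            pts = pts[hull.vertices]
        except Exception:  # collinear point sets: fall back to all pairs
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).max()) + 1.0


def relative_error(measured: float, reference: float) -> float:
    """Absolute relative error in percent: |P - Pref| / Pref * 100.

    The absolute value is taken per lesion so under- and over-segmentation
    cannot cancel when errors are averaged.
    """
    if reference <= 0:
        raise ValueError("reference value must be positive")
    return abs(measured - reference) / reference * 100.0


def angle_error_percent(measured_deg: float, reference_deg: float) -> float:
    """Angle disagreement as a percentage of the 90-degree range.

    The raw relative error is ill-posed for reference angles near zero, so
    the angular difference (axial, wrapped to [0, 90]) is normalized by 90
    degrees instead.
    """
    d = abs(measured_deg - reference_deg) % 180.0
    d = min(d, 180.0 - d)
    return d / 90.0 * 100.0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks have Dice 1."""
    a = as_binary_mask(a)
    b = as_binary_mask(b, a.shape)
    na = int(a.sum())
    nb = int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def record_overlap(a: LesionRecord, b: LesionRecord) -> int:
    """Pixel overlap of two records via their crop rectangles (no full frames)."""
    ar0, ac0 = a.offset
    br0, bc0 = b.offset
    r0 = max(ar0, br0)
    c0 = max(ac0, bc0)
    r1 = min(ar0 + a.mask_crop.shape[0], br0 + b.mask_crop.shape[0])
    c1 = min(ac0 + a.mask_crop.shape[1], bc0 + b.mask_crop.shape[1])
    if r1 <= r0 or c1 <= c0:
        return 0
    ca = a.mask_crop[r0 - ar0 : r1 - ar0, c0 - ac0 : c1 - ac0]
    cb = b.mask_crop[r0 - br0 : r1 - br0, c0 - bc0 : c1 - bc0]
    return int((ca & cb).sum())


def record_dice(a: LesionRecord, b: LesionRecord) -> float:
    inter = record_overlap(a, b)
    na, nb = a.area_px, b.area_px
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def geometry_report(
    pairs: Sequence[tuple[LesionRecord, LesionRecord]],
    mm_per_px: float,
    boundaries_mm: Sequence[float] = (1.0, 3.0),
) -> pd.DataFrame:
    """Mean per-parameter relative errors and Dice, per size stratum.

    ``pairs`` are matched (detected, reference) records; strata are assigned
    from the *reference* equivalent diameter on half-open intervals
    ``[low, high)`` over ``boundaries_mm``, with an unbounded final stratum.
    Lesions below the first boundary are excluded. Empty strata are simply
    absent from the table.
    """
    from .evaluation import stratify, stratum_names

    rows = []
    for det, ref in pairs:
        g_det = measure(det.mask_crop, mm_per_px)  # geometry is translation invariant
        g_ref = measure(ref.mask_crop, mm_per_px)
        if g_ref.angle_defined and g_det.angle_defined:
            angle_err = angle_error_percent(g_det.ellipse_angle_deg, g_ref.ellipse_angle_deg)
        else:
            angle_err = 0.0
        rows.append(
            {
                "ref_diameter_mm": g_ref.equivalent_diameter_mm,
                "area_err": relative_error(g_det.area_mm2, g_ref.area_mm2),
                "eq_diam_err": relative_error(
                    g_det.equivalent_diameter_mm, g_ref.equivalent_diameter_mm
                ),
                "major_err": relative_error(g_det.ellipse_major_mm, g_ref.ellipse_major_mm),
                "minor_err": relative_error(g_det.ellipse_minor_mm, g_ref.ellipse_minor_mm),
                "angle_err": angle_err,
                "dice": record_dice(det, ref),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(
            columns=["stratum", "n", "area_err", "eq_diam_err", "major_err", "minor_err", "angle_err", "dice"]
        )
    df["stratum"] = stratify(df["ref_diameter_mm"].to_numpy(), boundaries_mm)
    df = df[df["stratum"] != ""]
    grouped = (
        df.groupby("stratum", sort=False)
        .agg(
            n=("area_err", "size"),
            area_err=("area_err", "mean"),
            eq_diam_err=("eq_diam_err", "mean"),
            major_err=("major_err", "mean"),
            minor_err=("minor_err", "mean"),
            angle_err=("angle_err", "mean"),
            dice=("dice", "mean"),
        )
        .reset_index()
    )
    order = {name: i for i, name in enumerate(stratum_names(boundaries_mm))}
    return grouped.sort_values("stratum", key=lambda s: s.map(order)).reset_index(drop=True)
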