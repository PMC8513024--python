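"""Template-bank lesion detection by normalized cross-correlation.

A small bank of grayscale lesion templates (dark blobs of a few physical
sizes) is slid across the green channel. For each template the normalized
cross-correlation

    gamma(u, v) = sum (f - fbar)(t - tbar) /
                  [ sum (f - fbar)^2 * sum (t - tbar)^2 ]^0.5

is computed over every full-overlap placement; gamma is invariant to local
brightness and contrast, so a template matches lesions regardless of skin
tone. Negative correlation is discarded, the map is thresholded, and
surviving blobs become candidate spots if their equivalent diameter exceeds
1 mm and their area does not exceed the biggest template. Spots are then
deduplicated (greedy, highest gamma first), spots near the skin boundary
dropped, and each survivor segmented with a region-based active contour on
the luma channel, seeded at the spot centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from skimage.segmentation import disk_level_set, morphological_chan_vese

from .core import (
    LesionRecord,
    RgbImage,
    as_binary_mask,
    connected_components,
    labels_from_records,
    luma,
    mm_to_px,
)

__all__ = [
    "Template",
    "TemplateBank",
    "CorrelationMap",
    "CorrelationParams",
    "Spot",
    "ncc",
    "find_spots",
    "remove_duplicates",
    "remove_close_to_background",
    "active_contour_segment",
    "detect_correlation",
]


@dataclass(frozen=True)
class Template:
    """One grayscale lesion pattern with its physical pixel pitch."""

    name: str
    pixels: np.ndarray
    mm_per_px: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError("template must be a 2-D grayscale patch")
        if px.std() == 0:
            raise ValueError(f"template {self.name!r} has zero variance")
        object.__setattr__(self, "pixels", px)

    @property
    def area_px(self) -> int:
        return self.pixels.size


@dataclass(frozen=True)
class TemplateBank:
    templates: tuple[Template, ...]

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("template bank is empty")

    @property
    def largest_area_px(self) -> int:
        return max(t.area_px for t in self.templates)

    @property
    def largest_side_px(self) -> int:
        return max(max(t.pixels.shape) for t in self.templates)

    @classmethod
    def gaussian_blobs(
        cls,
        diameters_mm: tuple[float, ...] = (1.5, 3.0, 6.0),
        mm_per_px: float = 0.1,
        skin_level: float = 150.0,
        depth: float = 60.0,
    ) -> "TemplateBank":
        """Synthetic bank: radially symmetric dark blobs at several scales.

        Stands in for patient-derived template patches; NCC is affine
        invariant so only the blob profile matters, not the levels.
        """
        templates = []
        for d in diameters_mm:
            radius = mm_to_px(d / 2, mm_per_px)
            half = int(round(radius * 1.6))
            yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
            rho = np.hypot(yy, xx) / radius
            profile = np.exp(-(rho**2) / 0.5)  # ~Gaussian lesion profile
            patch = skin_level - depth * profile
            templates.append(Template(f"blob_{d:g}mm", patch, mm_per_px))
        return cls(tuple(templates))


@dataclass(frozen=True)
class CorrelationMap:
    """gamma(u, v) over all full-overlap placements of one template."""

    gamma: np.ndarray
    template_name: str
    template_shape: tuple[int, int]

    def to_image_coords(self, u: int, v: int) -> tuple[int, int]:
        """Map a placement (top-left) to the template-centre image pixel."""
        return (u + self.template_shape[0] // 2, v + self.template_shape[1] // 2)


@dataclass(frozen=True)
class Spot:
    """A candidate lesion centre in image coordinates."""

    row: int
    col: int
    gamma: float
    template_name: str = ""
    template_shape: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class CorrelationParams:
    corr_threshold: float = 0.5
    min_diameter_mm: float = 1.0
    min_dist_px: int | None = None  # default: radius of the largest template
    background_margin_px: int = 10
    ac_iterations: int = 200
    ac_init_radius_px: int = 3
    ac_smoothing: int = 1
    ac_min_contrast: float = 10.0
    ac_min_area_px: int = 9


def ncc(image_channel: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Normalized cross-correlation map over full-overlap placements.

    Placements where the image region under the template is constant (the
    0/0 case) are defined as gamma = 0. Implemented with summed-area tables
    for the local image mean/variance and a direct/FFT correlation for the
    numerator, so it scales to whole-body image sizes.
    """
    f = np.asarray(image_channel, dtype=np.float64)
    t = np.asarray(template, dtype=np.float64)
    if t.shape[0] > f.shape[0] or t.shape[1] > f.shape[1]:
        raise ValueError("template larger than image")
    t0 = t - t.mean()
    t_energy = float(np.sum(t0**2))
    if t_energy == 0:
        raise ValueError("flat template: correlation undefined")

    n = t.size
    # numerator: sum f * (t - tbar) over the window equals sum (f - fbar)(t - tbar)
    num = signal.correlate(f, t0, mode="valid")
    # local sums of f and f^2 via summed-area tables (exact for integer input)
    s1 = _window_sums(f, t.shape)
    s2 = _window_sums(f**2, t.shape)
    var = s2 - s1**2 / n
    np.maximum(var, 0.0, out=var)
    denom = np.sqrt(var * t_energy)
    flat = denom <= 1e-8 * n
    denom[flat] = 1.0
    gamma = num / denom
    gamma[flat] = 0.0
    return np.clip(gamma, -1.0, 1.0)


def _window_sums(arr: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    """Sliding-window sums (valid mode) via a padded 2-D cumulative sum."""
    th, tw = window
    c = np.cumsum(np.cumsum(np.pad(arr, ((1, 0), (1, 0))), axis=0), axis=1)
    return c[th:, tw:] - c[:-th, tw:] - c[th:, :-tw] + c[:-th, :-tw]


def correlate_template(image_channel: np.ndarray, template: Template) -> CorrelationMap:
    return CorrelationMap(
        gamma=ncc(image_channel, template.pixels),
        template_name=template.name,
        template_shape=template.pixels.shape,
    )


def find_spots(
    cmap: CorrelationMap,
    corr_threshold: float,
    mm_per_px: float,
    max_area_px: int,
    min_diameter_mm: float = 1.0,
) -> list[Spot]:
    """Threshold the correlation map and extract one spot per blob.

    Negative correlation is zeroed first; blobs must be bigger than
    ``min_diameter_mm`` equivalent diameter (strict) and no bigger than the
    largest template. Each surviving blob yields a spot at its gamma argmax,
    mapped to image coordinates at the template centre.
    """
    if not 0.0 < corr_threshold < 1.0:
        raise ValueError("corr_threshold must lie in (0, 1)")
    g = np.where(cmap.gamma < 0, 0.0, cmap.gamma)
    labels = connected_components(g >= corr_threshold, connectivity=8)
    k = int(labels.max(initial=0))
    if k == 0:
        return []
    min_area_px = np.pi * (min_diameter_mm / 2.0) ** 2 / mm_per_px**2
    spots: list[Spot] = []
    for slc, lab in zip(ndimage.find_objects(labels), range(1, k + 1)):
        comp = labels[slc] == lab
        area = int(comp.sum())
        if area <= min_area_px or area > max_area_px:
            continue
        local = np.where(comp, g[slc], -np.inf)
        u, v = np.unravel_index(int(np.argmax(local)), local.shape)
        u += slc[0].start
        v += slc[1].start
        r, c = cmap.to_image_coords(u, v)
        spots.append(
            Spot(
                row=r,
                col=c,
                gamma=float(g[u, v]),
                template_name=cmap.template_name,
                template_shape=cmap.template_shape,
            )
        )
    return spots


def remove_duplicates(spots: list[Spot], min_dist_px: float) -> list[Spot]:
    """Greedy non-maximum suppression on spot centres.

    Spots are visited by descending gamma (ties: smaller (row, col) first, so
    the result does not depend on template order in the bank); a spot within
    ``min_dist_px`` of an already kept spot is suppressed.
    """
    if min_dist_px < 0:
        raise ValueError("min_dist_px must be >= 0")
    ordered = sorted(spots, key=lambda s: (-s.gamma, s.row, s.col))
    kept: list[Spot] = []
    for s in ordered:
        if all(np.hypot(s.row - k.row, s.col - k.col) > min_dist_px for k in kept):
            kept.append(s)
    return kept


def remove_close_to_background(
    spots: list[Spot], skin: np.ndarray, margin_px: float
) -> list[Spot]:
    """Drop spots whose centre is within ``margin_px`` of any non-skin pixel.

    Lesion-like responses hugging the silhouette or underwear edge are
    usually shading artefacts; the skin mask's Euclidean distance transform
    gives each centre's clearance.
    """
    if margin_px < 0:
        raise ValueError("margin_px must be >= 0")
    skin = as_binary_mask(skin)
    dist = ndimage.distance_transform_edt(skin)
    return [s for s in spots if dist[s.row, s.col] > margin_px]


def active_contour_segment(
    y_channel: np.ndarray,
    seed: tuple[int, int],
    params: CorrelationParams | None = None,
    skin: np.ndarray | None = None,
    crop_half_px: int = 80,
) -> tuple[np.ndarray, bool]:
    """Region-based active contour from a seed on the luma channel.

    A small disk at the seed is evolved by morphological Chan-Vese updates
    inside a crop centred on the seed; the connected region containing the
    seed is returned as a full-frame mask. The second return value flags a
    degenerate result (no stable region: insufficient contrast between the
    inside and outside means, or collapse below a minimal area), in which
    case the mask is empty.
    """
    params = params or CorrelationParams()
    y = np.asarray(y_channel, dtype=np.float64)
    r, c = seed
    if not (0 <= r < y.shape[0] and 0 <= c < y.shape[1]):
        raise ValueError(f"seed {seed} outside image {y.shape}")
    if skin is not None and not as_binary_mask(skin, y.shape)[r, c]:
        raise ValueError(f"seed {seed} lies on non-skin")

    r0 = max(0, r - crop_half_px)
    c0 = max(0, c - crop_half_px)
    crop = y[r0 : r0 + 2 * crop_half_px + 1, c0 : c0 + 2 * crop_half_px + 1]
    init = disk_level_set(crop.shape, center=(r - r0, c - c0), radius=params.ac_init_radius_px)
    ls = morphological_chan_vese(
        crop,
        num_iter=params.ac_iterations,
        init_level_set=init,
        smoothing=params.ac_smoothing,
    ).astype(bool)

    inside = ls if ls[r - r0, c - c0] else ~ls
    mu_in = crop[inside].mean() if inside.any() else 0.0
    mu_out = crop[~inside].mean() if (~inside).any() else mu_in
    full = np.zeros(y.shape, dtype=bool)
    if abs(mu_in - mu_out) < params.ac_min_contrast:
        return full, True
    labels, _ = ndimage.label(inside, structure=np.ones((3, 3), dtype=bool))
    region = labels == labels[r - r0, c - c0]
    if labels[r - r0, c - c0] == 0 or int(region.sum()) < params.ac_min_area_px:
        return full, True
    # the seed's region must be the locally darker phase (lesions are darker)
    if crop[region].mean() > crop[~region].mean():
        return full, True
    full[r0 : r0 + crop.shape[0], c0 : c0 + crop.shape[1]] = region
    return full, False


def detect_correlation(
    image: RgbImage,
    skin: np.ndarray,
    bank: TemplateBank,
    params: CorrelationParams | None = None,
) -> tuple[np.ndarray, list[LesionRecord]]:
    """Full correlation pipeline; returns a label mask and lesion records.

    Green channel NCC against every template, spot extraction, duplicate
    suppression across templates, boundary filtering, then active-contour
    segmentation of each spot on luma.
    """
    params = params or CorrelationParams()
    skin = as_binary_mask(skin, image.shape)
    green = image.green.astype(np.float64)

    all_spots: list[Spot] = []
    for template in bank.templates:
        cmap = correlate_template(green, template)
        all_spots.extend(
            find_spots(
                cmap,
                params.corr_threshold,
                image.mm_per_px,
                bank.largest_area_px,
                params.min_diameter_mm,
            )
        )
    min_dist = params.min_dist_px if params.min_dist_px is not None else bank.largest_side_px // 2
    spots = remove_duplicates(all_spots, min_dist)
    spots = remove_close_to_background(spots, skin, params.background_margin_px)

    y = luma(image)
    crop_half = max(40, bank.largest_side_px)
    records: list[LesionRecord] = []
    for spot in spots:
        if not skin[spot.row, spot.col]:
            continue
        mask, degenerate = active_contour_segment(
            y, (spot.row, spot.col), params, skin=skin, crop_half_px=crop_half
        )
        if degenerate or not mask.any():
            continue
        mask &= skin
        if not mask.any():
            continue
        rows, cols = np.nonzero(mask)
        rmin, rmax = rows.min(), rows.max()
        cmin, cmax = cols.min(), cols.max()
        records.append(
            LesionRecord(
                id=len(records) + 1,
                centroid=(float(rows.mean()), float(cols.mean())),
                mask_crop=mask[rmin : rmax + 1, cmin : cmax + 1],
                offset=(int(rmin), int(cmin)),
                sources=frozenset(["correlation"]),
                score=spot.gamma,
            )
        )
    labels = labels_from_records(records, image.shape)
    return labels, records
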