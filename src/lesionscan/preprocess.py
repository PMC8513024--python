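"""Skin-region detection and hair suppression.

Whole-body photographs contain a non-skin background, underwear and hair;
everything downstream (histogram modelling, template correlation, box
segmentation) assumes it only ever sees skin. ``detect_skin`` applies an
explicit per-pixel RGB rule followed by morphological clean-up, and
``remove_hair`` applies a dull-razor style pipeline (morphological closing
with oriented linear elements, residue thresholding, elongation filtering and
interpolation of the hair pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .core import RgbImage, as_binary_mask, luma

__all__ = ["SkinRule", "detect_skin", "remove_hair"]


@dataclass(frozen=True)
class SkinRule:
    """Per-pixel RGB skin classifier.

    The defaults are the classic explicit-RGB rule for skin under uniform
    daylight-like illumination: R > 95, G > 40, B > 20, a channel spread
    (max - min) above 15, R - G > 15 and R dominating both G and B. All
    bounds are exposed so the rule can be re-tuned per acquisition setup.
    """

    r_min: int = 95
    g_min: int = 40
    b_min: int = 20
    min_spread: int = 15
    min_r_minus_g: int = 15

    def __post_init__(self) -> None:
        for name in ("r_min", "g_min", "b_min", "min_spread", "min_r_minus_g"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name}={v} outside [0, 255]")

    def evaluate(self, pixels: np.ndarray) -> np.ndarray:
        """Apply the raw per-pixel predicate (no morphology)."""
        rgb = pixels.astype(np.int16)
        r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
        spread = rgb.max(axis=-1) - rgb.min(axis=-1)
        return (
            (r > self.r_min)
            & (g > self.g_min)
            & (b > self.b_min)
            & (spread > self.min_spread)
            & (r - g > self.min_r_minus_g)
            & (r > g)
            & (r > b)
        )


def detect_skin(
    image: RgbImage,
    rule: SkinRule | None = None,
    opening_radius_px: int = 2,
) -> np.ndarray:
    """Binary skin mask: rule pixels, opened, with holes filled.

    Pixels marked 0 (background, underwear, deep shadow) are excluded from
    all downstream analysis. The opening removes speckle; hole filling keeps
    dark lesions — which the rule may reject — inside the skin region.
    """
    if image.pixels.size == 0:
        raise ValueError("empty image")
    rule = rule or SkinRule()
    mask = rule.evaluate(image.pixels)
    if opening_radius_px > 0:
        mask = morphology.opening(mask, morphology.disk(opening_radius_px))
    mask = ndimage.binary_fill_holes(mask)
    return as_binary_mask(mask, image.shape)


def _linear_selems(length: int, n_orientations: int = 4) -> list[np.ndarray]:
    """Linear structuring elements at evenly spaced orientations."""
    selems = []
    for k in range(n_orientations):
        theta = np.pi * k / n_orientations
        c, s = np.cos(theta), np.sin(theta)
        half = (length - 1) / 2
        rr = np.round(np.linspace(-half, half, length) * s).astype(int)
        cc = np.round(np.linspace(-half, half, length) * c).astype(int)
        se = np.zeros((2 * abs(rr).max() + 1, 2 * abs(cc).max() + 1), dtype=bool)
        se[rr + abs(rr).max(), cc + abs(cc).max()] = True
        selems.append(se)
    return selems


def remove_hair(
    image: RgbImage,
    kernel_length_px: int = 15,
    inpaint_radius_px: int = 2,
    residue_threshold: int = 15,
    n_orientations: int = 4,
    min_elongation: float = 3.0,
    prefilter_sigma: float = 1.0,
) -> tuple[RgbImage, np.ndarray]:
    """Dull-razor hair removal.

    Thin dark hairs vanish under grayscale morphological closing with a
    linear structuring element aligned across them; the closing residue
    (closed minus original) localises them. Residue pixels above
    ``residue_threshold`` gray levels whose connected components are
    elongated (major/minor axis ratio >= ``min_elongation``) form the hair
    mask; hair pixels are replaced by their nearest non-hair neighbours and
    smoothed, leaving all other pixels untouched.

    Returns the cleaned image and the (dilated) hair mask that was filled.
    """
    if kernel_length_px < 3:
        raise ValueError("kernel_length_px must be >= 3")
    gray = luma(image)
    if prefilter_sigma > 0:  # suppress skin micro-texture before the closing
        gray = ndimage.gaussian_filter(gray, prefilter_sigma)
    residue = np.zeros_like(gray)
    for se in _linear_selems(kernel_length_px, n_orientations):
        closed = ndimage.grey_closing(gray, footprint=se)
        np.maximum(residue, closed - gray, out=residue)
    raw = residue > residue_threshold

    hair = np.zeros_like(raw)
    labels = measure.label(raw, connectivity=2)
    for region in measure.regionprops(labels):
        minor = max(region.axis_minor_length, 1.0)
        if region.axis_major_length / minor >= min_elongation:
            hair[labels == region.label] = True

    if not hair.any():
        return image, hair

    dilated = morphology.dilation(hair, morphology.disk(inpaint_radius_px))
    # nearest-non-hair fill via the EDT's feature transform, then a few
    # diffusion relaxation passes anchored on the surrounding skin so the
    # filled band blends into the local texture rather than showing seams
    _, (ir, ic) = ndimage.distance_transform_edt(dilated, return_indices=True)
    filled = image.pixels.astype(np.float64)
    filled[dilated] = image.pixels[ir[dilated], ic[dilated]]
    for _ in range(4):
        smoothed = ndimage.gaussian_filter(filled, sigma=(1.2, 1.2, 0))
        filled[dilated] = smoothed[dilated]
    out = image.pixels.copy()
    out[dilated] = np.clip(np.round(filled[dilated]), 0, 255).astype(np.uint8)
    return image.with_pixels(out), dilated
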