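"""Deterministic synthetic skin scenes with known ground truth.

Real whole-body photographs are sensitive medical data; the generator stands
in for them with scenes that reproduce the image statistics the detectors
rely on: per-channel near-Gaussian skin intensities, lesions as locally
darker soft-edged blobs (the drop strongest in green and blue, so they form
the low-intensity histogram tail), thin dark hair streaks, and a flat gray
non-skin background band. Every scene is fully determined by its spec and
seed, and ships its truth label mask and lesion table, closing the
generator → detector → evaluation loop with no external inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line_aa

from .core import RgbImage, mm_to_px

__all__ = ["LesionSpec", "HairSpec", "BackgroundSpec", "SceneSpec", "Scene", "generate", "standard_suite"]

#: default per-channel skin model, chosen once for all fixtures: a light
#: skin tone whose green/blue levels leave a 60-gray-level dynamic range for
#: lesion contrast. sigma=8 keeps the channel histograms clearly unimodal.
DEFAULT_SKIN_MEAN = (190.0, 150.0, 120.0)
DEFAULT_SKIN_SIGMA = 8.0
#: default lesion intensity drop (R, G, B): strongest in green and blue,
#: where the histogram tail is most visible.
DEFAULT_DROP = (30.0, 60.0, 55.0)


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[int, int]  # (row, col)
    diameter_mm: float
    drop: tuple[float, float, float] = DEFAULT_DROP
    softness: float = 0.1  # fraction of the radius over which the drop fades


@dataclass(frozen=True)
class HairSpec:
    count: int = 8
    width_px: int = 2
    darkness: float = 80.0
    length_px: int = 180


@dataclass(frozen=True)
class BackgroundSpec:
    """Flat gray band on one side of the frame (the studio backdrop)."""

    side: str = "left"  # left|right|top|bottom|none
    width_px: int = 64
    gray: int = 128


@dataclass(frozen=True)
class SceneSpec:
    height: int = 512
    width: int = 512
    mm_per_px: float = 0.1
    skin_mean: tuple[float, float, float] = DEFAULT_SKIN_MEAN
    skin_sigma: float = DEFAULT_SKIN_SIGMA
    texture_scale_px: float = 2.5  # skin texture correlation length (~0.25 mm)
    lesions: tuple[LesionSpec, ...] = ()
    hair: HairSpec | None = None
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    seed: int = 0
    allow_overlap: bool = False
    name: str = "scene"


@dataclass
class Scene:
    spec: SceneSpec
    image: RgbImage
    truth_labels: np.ndarray
    truth_table: pd.DataFrame
    skin_truth: np.ndarray  # true skin mask (non-background)
    clean_image: RgbImage  # same scene without hair, for hair-removal oracles


def _background_mask(spec: SceneSpec) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    bg = spec.background
    if bg is None or bg.side == "none" or bg.width_px <= 0:
        return mask
    if bg.side == "left":
        mask[:, : bg.width_px] = True
    elif bg.side == "right":
        mask[:, -bg.width_px :] = True
    elif bg.side == "top":
        mask[: bg.width_px, :] = True
    elif bg.side == "bottom":
        mask[-bg.width_px :, :] = True
    else:
        raise ValueError(f"unknown background side {bg.side!r}")
    return mask


def _lesion_profile(spec: SceneSpec, lesion: LesionSpec) -> tuple[np.ndarray, np.ndarray, tuple[slice, slice]]:
    """Radial drop factor in [0, 1] and the truth disk, on a tight crop."""
    radius_px = lesion.diameter_mm / 2.0 / spec.mm_per_px
    half = int(np.ceil(radius_px)) + 1
    r0, c0 = lesion.center
    sl = (slice(r0 - half, r0 + half + 1), slice(c0 - half, c0 + half + 1))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    rho = np.hypot(yy, xx) / radius_px
    soft = max(lesion.softness, 1e-6)
    # flat core, cosine shoulder fading to zero at the rim
    factor = np.clip((1.0 - rho) / soft, 0.0, 1.0)
    factor = 0.5 - 0.5 * np.cos(np.pi * factor)
    disk = rho <= 1.0
    return factor, disk, sl


def generate(spec: SceneSpec) -> Scene:
    """Render a scene; byte-identical output for equal specs.

    Raises if a lesion extends outside the skin region or two lesions
    overlap (unless ``allow_overlap``).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    pixels = np.empty((h, w, 3), dtype=np.float64)
    for ch in range(3):
        # spatially correlated Gaussian texture: skin intensity varies
        # smoothly at this scale; the per-pixel marginal keeps sigma
        field = rng.normal(0.0, 1.0, size=(h, w))
        if spec.texture_scale_px > 0:
            field = ndimage.gaussian_filter(field, spec.texture_scale_px)
            field /= field.std()
        pixels[:, :, ch] = spec.skin_mean[ch] + spec.skin_sigma * field

    bg = _background_mask(spec)
    skin_truth = ~bg

    truth_labels = np.zeros((h, w), dtype=np.int32)
    rows = []
    for k, lesion in enumerate(spec.lesions, start=1):
        factor, disk, sl = _lesion_profile(spec, lesion)
        if (
            sl[0].start < 0
            or sl[1].start < 0
            or sl[0].stop > h
            or sl[1].stop > w
            or bg[sl][disk].any()
        ):
            raise ValueError(f"lesion {k} at {lesion.center} extends outside the skin region")
        if not spec.allow_overlap and (truth_labels[sl][disk] != 0).any():
            raise ValueError(f"lesion {k} overlaps a previous lesion")
        for ch in range(3):
            pixels[:, :, ch][sl] -= lesion.drop[ch] * factor
        truth_labels[sl][disk] = k
        area_mm2 = int(disk.sum()) * spec.mm_per_px**2
        rows.append(
            {
                "id": k,
                "row": lesion.center[0],
                "col": lesion.center[1],
                "diameter_mm": lesion.diameter_mm,
                "area_mm2": area_mm2,
                "equivalent_diameter_mm": 2.0 * np.sqrt(area_mm2 / np.pi),
            }
        )

    clean = pixels.copy()
    if spec.hair is not None and spec.hair.count > 0:
        _draw_hairs(pixels, skin_truth, spec.hair, rng)

    for arr in (pixels, clean):
        arr[bg] = spec.background.gray
    image = RgbImage(np.clip(np.round(pixels), 0, 255).astype(np.uint8), spec.mm_per_px)
    clean_image = RgbImage(np.clip(np.round(clean), 0, 255).astype(np.uint8), spec.mm_per_px)

    truth_table = pd.DataFrame(
        rows,
        columns=["id", "row", "col", "diameter_mm", "area_mm2", "equivalent_diameter_mm"],
    )
    return Scene(
        spec=spec,
        image=image,
        truth_labels=truth_labels,
        truth_table=truth_table,
        skin_truth=skin_truth,
        clean_image=clean_image,
    )


def _draw_hairs(pixels: np.ndarray, skin: np.ndarray, hair: HairSpec, rng: np.random.Generator) -> None:
    """Dark anti-aliased polylines (3 jointed segments each) across the skin."""
    h, w = skin.shape
    for _ in range(hair.count):
        r = float(rng.uniform(0, h - 1))
        c = float(rng.uniform(0, w - 1))
        theta = float(rng.uniform(0, 2 * np.pi))
        for _segment in range(3):
            seg = hair.length_px / 3.0
            r2 = float(np.clip(r + seg * np.sin(theta), 0, h - 1))
            c2 = float(np.clip(c + seg * np.cos(theta), 0, w - 1))
            rr, cc, val = line_aa(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
            for off_r in range(hair.width_px):
                rr_o = np.clip(rr + off_r, 0, h - 1)
                on_skin = skin[rr_o, cc]
                drop = hair.darkness * val[on_skin]
                for ch in range(3):
                    pixels[rr_o[on_skin], cc[on_skin], ch] -= drop
            r, c = r2, c2
            theta += float(rng.uniform(-0.4, 0.4))
    np.clip(pixels, 0, 255, out=pixels)


def standard_suite(seed: int = 0) -> list[SceneSpec]:
    """The fixed five-scene battery used by the tests and acceptance runs.

    Scenes: lesion-free; ten lesions balanced over the 1-2 / 2-5 / >5 mm
    strata; hairy; lesions at graded distances from the background edge
    (including one whose centroid is within 10 px of non-skin); low-contrast
    lesions. Together these cover the known failure modes: speckle false
    alarms, hair occlusion, silhouette proximity and weak contrast.
    """
    mm = 0.1
    bg_w = 64

    def mk(name, lesions=(), hair=None, seed_offset=0):
        return SceneSpec(
            name=name,
            lesions=tuple(lesions),
            hair=hair,
            seed=seed + seed_offset,
            mm_per_px=mm,
            background=BackgroundSpec(side="left", width_px=bg_w),
        )

    strata_lesions = [
        LesionSpec((80, 140), 1.2),
        LesionSpec((80, 280), 1.5),
        LesionSpec((80, 420), 1.8),
        LesionSpec((210, 140), 2.5),
        LesionSpec((210, 280), 3.0),
        LesionSpec((210, 430), 3.5),
        LesionSpec((340, 150), 4.0),
        LesionSpec((340, 320), 4.5),
        LesionSpec((460, 160), 5.5),
        LesionSpec((450, 380), 6.5),
    ]
    hairy_lesions = [
        LesionSpec((100, 160), 2.5),
        LesionSpec((120, 400), 3.0),
        LesionSpec((260, 250), 3.5),
        LesionSpec((390, 150), 4.0),
        LesionSpec((420, 400), 5.0),
    ]
    # graded clearance from the background edge at col 64; the first lesion's
    # centroid sits 9 px from non-skin (inside the 10 px margin)
    boundary_lesions = [
        LesionSpec((100, 64 + 8), 1.5),
        LesionSpec((220, 64 + 25), 3.0),
        LesionSpec((340, 64 + 50), 4.0),
        LesionSpec((440, 64 + 105), 5.0),
    ]
    low_contrast = tuple(
        LesionSpec(center, d, drop=(18.0, 40.0, 36.0))
        for center, d in [((110, 160), 2.5), ((150, 400), 3.0), ((300, 260), 4.0), ((430, 380), 5.0)]
    )
    return [
        mk("lesion_free"),
        mk("strata_balanced", strata_lesions, seed_offset=1),
        mk("hairy", hairy_lesions, hair=HairSpec(), seed_offset=2),
        mk("boundary", boundary_lesions, seed_offset=3),
        mk("low_contrast", low_contrast, seed_offset=4),
    ]
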