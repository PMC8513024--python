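# Methods

This note records the models, parameter choices and numerical conventions
behind `lesionscan`, and what the synthetic fixtures do and do not establish.

## Problem setting

Whole-body photographs (a 20 MP camera at ~80 cm) are analysed to find
pigmented lesions from ~1 mm upward. All physical thresholds are expressed
in millimetres and converted through an explicit `mm_per_px` calibration
(nearest-pixel rounding, minimum 1 px); the package never guesses the scale
from image metadata. Coordinates are `(row, col)`, 0-based, top-left origin;
boxes store top-left corner plus inclusive pixel extents.

## Preprocessing

**Skin mask.** An explicit per-pixel RGB rule (defaults R>95, G>40, B>20,
max−min>15, R−G>15, R>G, R>B) followed by a radius-2 morphological opening
and hole filling. The hole filling is load-bearing: dark lesions can fail
the raw rule and must remain inside the analysed region. The rule's bounds
are configuration values because any change of camera or illumination
requires re-tuning.

**Hair removal (dull-razor style).** Luma is smoothed (σ=1) and closed with
15 px linear structuring elements at 4 orientations; the maximum closing
residue localises thin dark structures. Residue above 15 gray levels forms
candidate components, kept only if elongated (moment axis ratio ≥ 3) so
compact lesions are never treated as hair. The hair mask is dilated by 2 px
and filled by nearest-non-hair values (Euclidean feature transform) followed
by four Gaussian relaxation passes (σ=1.2) anchored on the surrounding skin
— a deterministic diffusion fill; pixels outside the dilated mask are
untouched by construction.

## Histogram-tail detector

Tiles are 128 px squares with 50 % overlap (every interior pixel is seen by
four tiles), so a lesion up to roughly a quarter of a tile stays a histogram
minority in at least one covering tile. Tiles with under 25 % skin pixels
are skipped. Per tile, green and blue histograms over skin pixels are
smoothed with a 5-bin moving average (reflective boundaries, mass
preserving), and thresholded at `2·mode − max`:

* `mode` is the smoothed peak, ties resolved to the lowest intensity
  (a smaller width flags fewer pixels);
* `max` is read as the highest *populated* intensity (the right edge), not
  the peak count — the only reading that yields a width and matches a tail
  that appears on the dark side. To resist single-pixel outliers the right
  edge is taken at the 99.9th percentile of the smoothed distribution
  (configurable; the 100th percentile reproduces the literal rule).

A constant tile degenerates to `th = mode`, and with strict `<` comparisons
flags nothing. Tile decisions are OR-combined (a voting mode is available
but off by default: overlap-count voting would demand every covering tile to
agree at lesion borders where tiles disagree legitimately). Components below
1 mm equivalent diameter are dropped, mirroring the correlation detector's
size rule. On pure-Gaussian tiles the threshold sits ≈3σ below the mode, so
the expected false-flag rate per channel is ~10⁻³ and the conjunction over
two channels suppresses nearly all speckle before the size filter.

## Correlation detector

Templates are radially symmetric dark blobs (`exp(−ρ²/0.5)` profile) at
diameters 1.5/3/6 mm rendered at the image calibration; since the
normalized cross-correlation is invariant to affine intensity maps, only the
profile matters. The NCC is computed with summed-area tables for the local
mean/variance and an FFT/direct correlation for the numerator; placements
with zero local variance define γ=0. The binarisation threshold is 0.5
(half-way between "no linear relation" and a perfect match; not stated by
any source, exposed in config). Spot blobs must exceed 1 mm equivalent
diameter (strict) and not exceed the largest template's area. Duplicate
spots are removed greedily by descending γ with lexicographic (row, col)
tie-break, radius = half the largest template side, which makes the result
independent of template order. Spots whose centre lies within 10 px of
non-skin are discarded (distance transform of the skin mask) — responses
hugging the silhouette are shading artefacts.

Segmentation is `skimage.segmentation.morphological_chan_vese` (region-based
contour evolution by morphological updates — deterministic and
parameter-light), run for ≤200 iterations from a 3 px disk at the spot
centre, inside a crop centred on the seed. The connected region containing
the seed is returned; the result is flagged degenerate (empty mask) when the
inside/outside mean contrast is below 10 gray levels, when the region
collapses below 9 px, or when the seed region is not the locally darker
phase.

## Box adapter

Frames are 416 px squares with 118 px overlap, stride 298 px; final frames
shift inward so no frame leaves the image, and images smaller than one frame
record their padding deficit. NMS is greedy by descending confidence
(deterministic tie-break on box position) with IoU threshold 0.5. In-box
segmentation: green-channel crop, 5×5 median filter, Otsu threshold
(in-package implementation; ties resolve to the smallest threshold), darker
class, largest 8-connected component. Lesions are darker than skin
throughout, so dark polarity is the default with a config override. The
green channel is used everywhere a single channel is needed, for consistency
across the three detectors. The stub detector models each frame's skin
pixels robustly (median, 1.4826·MAD) and proposes boxes around components
darker than median − 3.5σ; it exists so 2-of-3 fusion is exercisable without
trained weights, and any real model can replace it through the boxes-JSON
interface.

## Fusion

Records from different methods are grouped when their masks overlap by ≥1 px
(all methods emit masks in the same frame, so overlap is the natural
criterion; a centroid-distance rule is available). Groups are the transitive
closure of pairwise links; within a group each method contributes at most
one record — the one with the largest total overlap with the other methods'
members — and displaced records fall back to singletons. Votes count
distinct methods; groups with ≥2 votes survive, and the fused mask is the
union of the members' masks. When only two methods run, the 2-vote rule
degenerates to their intersection (documented; a `min_votes=1` override
falls back to single-method output).

## Evaluation

A reference lesion is TP when at least one detection overlaps it (any
overlap by default; an IoU ≥ 0.3 rule is available for stricter studies).
Detection–reference pairs are ranked by overlap and assigned greedily
one-to-one, so a single detection validates at most one reference; extra
detections on an already-validated reference are merged duplicates, counted
neither as TP nor FP. Detections overlapping no reference are FP, tallied
overall only (a false alarm has no reference size). Strata are half-open
`[low, high)` on the *reference* equivalent diameter — a 2.0 mm lesion falls
in "2–5" — with presets (1, 2, 5) mm for detection and (1, 3) mm for
geometry; lesions below the first boundary are excluded from stratum tables
but still protect overlapping detections from being counted FP.

## Morphometry

Area is the pixel count × `mm_per_px²`; equivalent diameter `2·√(area/π)`.
The ellipse comes from second central moments with a 1/12 px² diagonal
correction (a pixel is a unit square), axes `4·√eigenvalue`, angle of the
major axis measured from the +x (column) axis toward +y (down rows),
normalized to [−90°, 90°). Below eccentricity 0.1 the angle is meaningless
and its error is recorded as 0 and flagged. The maximum Feret diameter is
the largest distance between boundary-pixel centres plus 1 px of extent (a
single pixel has Feret 1 px), computed on the convex hull of the boundary.

Relative errors take the absolute value per lesion before averaging —
signed averaging would let under- and over-segmentation cancel. The angle
"relative" error is ill-posed near 0°, so angle disagreement is the axial
difference wrapped to [0°, 90°] and normalized by 90° (reported in percent
like the other parameters). Dice of two empty masks is defined as 1.

## Synthetic scenes

Each scene is fully determined by its spec and seed. Skin is a per-channel
Gaussian random field, means (190, 150, 120) for R/G/B, per-pixel σ = 8,
with a 2.5 px (0.25 mm) correlation length: skin tone varies smoothly at
pore scale rather than pixel-to-pixel (i.i.d. noise of that amplitude would
be a sensor property, and no interpolation could ever restore it after hair
removal). Lesions are subtractive radial blobs, drops (30, 60, 55) gray
levels in R/G/B — strongest in green and blue, which is where the histogram
tail is most visible — with a flat core and a cosine rim fading over 10 % of
the radius (≈0.25 mm on a 5 mm nevus; benign nevi have well-defined
borders). The truth mask is the full pigment disk, so every segmenter is
biased slightly small at the rim — deliberately, because that is the bias
union fusion is meant to correct. Hairs are dark anti-aliased polylines
(3 segments, ~2 px wide, 80 levels dark); the background is a flat neutral
band that fails the skin rule. Default calibration is 0.1 mm/px so
millimetre rules correspond to 10–70 px objects.

The fixed `standard_suite` battery is five 512×512 scenes: lesion-free;
ten lesions balanced over the 1–2/2–5/>5 mm strata; hairy; lesions at graded
clearances from the background edge (one centroid within 10 px of non-skin,
which the correlation detector's margin rule intentionally discards); and
low-contrast lesions (drops reduced by ~35 %).

What a green test establishes: the algorithms behave as specified on images
whose local statistics match their assumptions, at realistic sizes and
contrasts, including hair occlusion and boundary adjacency. What it does not
establish: performance on real skin — the generator has no body curvature or
illumination gradients, no jewellery/underwear confusers, no lesion texture
or colour heterogeneity, and its skin rule is satisfied by construction.
Clinical sensitivity/precision cannot be inferred from these fixtures.

## Known limitations

* The correlation detector needs templates within ~2× of the lesion scale;
  rotation/scale-invariant matching is out of scope.
* Sub-millimetre lesions are excluded by design (both detectors' 1 mm rule).
* The box stage's quality is bounded by the box source; the stub proposer is
  a deliberately simple stand-in, not a CNN substitute.
* Fusion requires at least two running methods to accept anything unless
  `min_votes` is lowered explicitly.
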