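import numpy as np
import pytest
from skimage.feature import match_template

from lesionscan.correlation_detector import (
    CorrelationMap,
    CorrelationParams,
    Spot,
    Template,
    TemplateBank,
    active_contour_segment,
    detect_correlation,
    find_spots,
    ncc,
    remove_close_to_background,
    remove_duplicates,
)
from lesionscan.preprocess import detect_skin
from lesionscan import synthgen


def brute_force_ncc(f, t):
    """Direct evaluation of the normalized cross-correlation sum."""
    f = np.asarray(f, dtype=float)
    t = np.asarray(t, dtype=float)
    th, tw = t.shape
    out = np.zeros((f.shape[0] - th + 1, f.shape[1] - tw + 1))
    t0 = t - t.mean()
    for u in range(out.shape[0]):
        for v in range(out.shape[1]):
            patch = f[u : u + th, v : v + tw]
            p0 = patch - patch.mean()
            denom = np.sqrt((p0**2).sum() * (t0**2).sum())
            out[u, v] = 0.0 if denom == 0 else (p0 * t0).sum() / denom
    return out


class TestNcc:
    def test_identical_patch_gives_one(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (12, 12)).astype(float)
        t = img[3:8, 4:9]
        gamma = ncc(img, t)
        assert gamma[3, 4] == pytest.approx(1.0, abs=1e-12)

    def test_contrast_inversion_gives_minus_one(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 200, (10, 10)).astype(float)
        t = 255.0 - img[2:6, 2:6]
        assert ncc(img, t)[2, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_constant_region_defined_as_zero(self):
        img = np.full((8, 8), 77.0)
        img[6, 6] = 90.0  # keep some variance elsewhere
        t = np.array([[1.0, 2.0], [3.0, 4.0]])
        gamma = ncc(img, t)
        assert gamma[0, 0] == 0.0

    def test_flat_template_rejected(self):
        with pytest.raises(ValueError):
            ncc(np.zeros((5, 5)), np.ones((2, 2)))

    def test_template_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            ncc(np.zeros((3, 3)), np.zeros((5, 5)))

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_and_library(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.integers(0, 256, (4 + seed, 6)).astype(float)
        t = rng.integers(0, 256, (2, 2)).astype(float)
        while t.std() == 0:
            t = rng.integers(0, 256, (2, 2)).astype(float)
        got = ncc(f, t)
        assert np.allclose(got, brute_force_ncc(f, t), atol=1e-10)
        lib = match_template(f, t, pad_input=False)
        assert np.allclose(got, lib, atol=1e-6)

    def test_bounded_by_one_everywhere(self):
        rng = np.random.default_rng(9)
        f = rng.integers(0, 256, (40, 40)).astype(float)
        t = rng.integers(0, 256, (7, 5)).astype(float)
        assert np.abs(ncc(f, t)).max() <= 1.0

    def test_invariant_to_affine_intensity_transform(self):
        rng = np.random.default_rng(10)
        f = rng.integers(10, 200, (15, 15)).astype(float)
        t = rng.integers(0, 256, (4, 4)).astype(float)
        assert np.allclose(ncc(f, t), ncc(2.5 * f + 10.0, t), atol=1e-10)


def _cmap(gamma, shape=(1, 1)):
    return CorrelationMap(gamma=np.asarray(gamma, dtype=float), template_name="t", template_shape=shape)


class TestFindSpots:
    def test_all_negative_map_yields_nothing(self):
        gamma = np.full((30, 30), -0.5)
        assert find_spots(_cmap(gamma), 0.5, 0.1, 10_000) == []

    def test_single_blob_spot_at_argmax(self):
        gamma = np.zeros((60, 60))
        yy, xx = np.mgrid[:60, :60]
        blob = np.hypot(yy - 30, xx - 30) <= 10  # equivalent diameter 2 mm at 0.1 mm/px
        gamma[blob] = 0.7
        gamma[30, 30] = 0.9
        (spot,) = find_spots(_cmap(gamma, (5, 5)), 0.5, 0.1, 10_000)
        assert (spot.row, spot.col) == (30 + 2, 30 + 2)  # template-centre offset
        assert spot.gamma == pytest.approx(0.9)

    def test_small_blob_rejected(self):
        gamma = np.zeros((40, 40))
        yy, xx = np.mgrid[:40, :40]
        gamma[np.hypot(yy - 20, xx - 20) <= 2.5] = 0.9  # ~0.5 mm blob
        assert find_spots(_cmap(gamma), 0.5, 0.1, 10_000) == []

    def test_blob_larger_than_biggest_template_rejected(self):
        gamma = np.zeros((60, 60))
        gamma[10:50, 10:50] = 0.9
        assert find_spots(_cmap(gamma), 0.5, 0.1, max_area_px=100) == []

    def test_threshold_bounds_validated(self):
        with pytest.raises(ValueError):
            find_spots(_cmap(np.zeros((5, 5))), 1.5, 0.1, 100)


class TestRemoveDuplicates:
    def test_identical_locations_collapse(self):
        spots = [Spot(5, 5, 0.9), Spot(5, 5, 0.8)]
        assert remove_duplicates(spots, 3) == [Spot(5, 5, 0.9)]

    def test_distant_spots_both_kept(self):
        spots = [Spot(0, 0, 0.9), Spot(50, 50, 0.8)]
        assert len(remove_duplicates(spots, 10)) == 2

    def test_chain_keeps_ends_when_middle_suppressed(self):
        # d(A,B) < min_dist, d(B,C) < min_dist, d(A,C) > min_dist
        a, b, c = Spot(0, 0, 0.9), Spot(0, 8, 0.5), Spot(0, 16, 0.7)
        kept = remove_duplicates([a, b, c], 10)
        assert kept == [a, c]

    def test_gamma_tie_breaks_on_position(self):
        a, b = Spot(4, 4, 0.8), Spot(4, 2, 0.8)
        assert remove_duplicates([a, b], 5) == [b]  # smaller (row, col) wins


class TestRemoveCloseToBackground:
    def test_center_of_all_skin_kept(self):
        skin = np.ones((50, 50), dtype=bool)
        assert remove_close_to_background([Spot(25, 25, 0.9)], skin, 10)

    def test_near_border_dropped(self):
        skin = np.ones((50, 50), dtype=bool)
        skin[:, :10] = False
        assert remove_close_to_background([Spot(25, 11, 0.9)], skin, 10) == []

    def test_graded_distances_match_distance_transform(self):
        from scipy import ndimage

        skin = np.ones((60, 120), dtype=bool)
        skin[:, :20] = False
        spots = [Spot(30, 20 + d, 0.9) for d in (1, 5, 10, 11, 30)]
        kept = remove_close_to_background(spots, skin, 10)
        dist = ndimage.distance_transform_edt(skin)
        expected = [s for s in spots if dist[s.row, s.col] > 10]
        assert kept == expected


class TestActiveContour:
    def _disk_image(self, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        img = np.full((101, 101), 150.0)
        yy, xx = np.mgrid[:101, :101]
        disk = np.hypot(yy - 50, xx - 50) <= 30  # 3 mm radius at 0.1 mm/px
        img[disk] = 90.0
        if noise:
            img += rng.normal(0, noise, img.shape)
        return img, disk

    def test_disk_segmented_with_high_dice(self):
        img, disk = self._disk_image()
        mask, degenerate = active_contour_segment(img, (50, 50))
        assert not degenerate
        inter = (mask & disk).sum()
        dice = 2 * inter / (mask.sum() + disk.sum())
        assert dice >= 0.90

    def test_featureless_region_is_degenerate(self):
        img = np.full((80, 80), 150.0)
        mask, degenerate = active_contour_segment(img, (40, 40))
        assert degenerate and not mask.any()

    def test_noisy_disk_area_within_15_percent(self):
        img, disk = self._disk_image(noise=10.0, seed=3)
        mask, degenerate = active_contour_segment(img, (50, 50))
        assert not degenerate
        assert abs(int(mask.sum()) - int(disk.sum())) / disk.sum() <= 0.15

    def test_seed_on_non_skin_rejected(self):
        img, _ = self._disk_image()
        skin = np.zeros(img.shape, dtype=bool)
        with pytest.raises(ValueError):
            active_contour_segment(img, (50, 50), skin=skin)

    def test_seed_outside_image_rejected(self):
        with pytest.raises(ValueError):
            active_contour_segment(np.zeros((10, 10)), (20, 20))


class TestTemplateBank:
    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            TemplateBank(())

    def test_flat_template_rejected(self):
        with pytest.raises(ValueError):
            Template("flat", np.ones((5, 5)), 0.1)

    def test_gaussian_bank_scales(self):
        bank = TemplateBank.gaussian_blobs((1.5, 3.0, 6.0), 0.1)
        assert len(bank.templates) == 3
        assert bank.largest_side_px == max(t.pixels.shape[0] for t in bank.templates)


@pytest.fixture(scope="module")
def scene():
    lesions = [
        synthgen.LesionSpec((60, 60), 2.5),
        synthgen.LesionSpec((60, 190), 3.0),
        synthgen.LesionSpec((190, 60), 4.0),
        synthgen.LesionSpec((190, 190), 5.0),
    ]
    return synthgen.generate(
        synthgen.SceneSpec(height=256, width=256, seed=31, lesions=tuple(lesions),
                           background=synthgen.BackgroundSpec(side="none"))
    )


class TestDetectCorrelation:
    def test_lesions_recovered(self, scene):
        skin = detect_skin(scene.image)
        bank = TemplateBank.gaussian_blobs((1.5, 3.0, 6.0), 0.1)
        labels, records = detect_correlation(scene.image, skin, bank)
        truth = scene.truth_labels
        hit = sum(
            bool(np.unique(labels[truth == k])[np.unique(labels[truth == k]) > 0].size)
            for k in range(1, truth.max() + 1)
        )
        assert hit == truth.max()
        assert len(records) == truth.max()  # no duplicates either

    def test_lesion_free_scene_clean(self):
        scene = synthgen.generate(
            synthgen.SceneSpec(height=256, width=256, seed=32,
                               background=synthgen.BackgroundSpec(side="none"))
        )
        skin = detect_skin(scene.image)
        bank = TemplateBank.gaussian_blobs((1.5, 3.0, 6.0), 0.1)
        labels, records = detect_correlation(scene.image, skin, bank)
        assert labels.max() == 0 and records == []

    def test_two_matching_templates_one_record(self, scene):
        skin = detect_skin(scene.image)
        bank = TemplateBank.gaussian_blobs((2.8, 3.2), 0.1)
        single = synthgen.generate(
            synthgen.SceneSpec(height=160, width=160, seed=33,
                               lesions=(synthgen.LesionSpec((80, 80), 3.0),),
                               background=synthgen.BackgroundSpec(side="none"))
        )
        labels, records = detect_correlation(single.image, detect_skin(single.image), bank)
        assert len(records) == 1

    def test_independent_of_template_order(self, scene):
        skin = detect_skin(scene.image)
        fwd = TemplateBank.gaussian_blobs((1.5, 3.0, 6.0), 0.1)
        rev = TemplateBank(tuple(reversed(fwd.templates)))
        labels_f, recs_f = detect_correlation(scene.image, skin, fwd)
        labels_r, recs_r = detect_correlation(scene.image, skin, rev)
        assert np.array_equal(labels_f, labels_r)
        assert [r.centroid for r in recs_f] == [r.centroid for r in recs_r]
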