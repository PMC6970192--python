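import numpy as np
import pytest

from radialpolarity import ImageRaster
from radialpolarity.segmentation import (
    dilate_labels,
    extract_rois,
    otsu_binarize,
    smooth_mask_borders,
    smooth_mean3x3,
    watershed_split,
)

from conftest import rasterize_disk


class TestSmoothMean3x3:
    def test_constant_image_unchanged(self):
        out = smooth_mean3x3(ImageRaster(np.full((6, 6), 7.0)))
        np.testing.assert_allclose(out.pixels, 7.0)

    def test_central_impulse_spreads_to_3x3_block(self):
        img = np.zeros((5, 5))
        img[2, 2] = 9.0
        out = smooth_mean3x3(ImageRaster(img)).pixels
        expected = np.zeros((5, 5))
        expected[1:4, 1:4] = 1.0
        np.testing.assert_allclose(out, expected)

    def test_linear_ramp_preserved_in_interior(self):
        img = np.tile(np.arange(8, dtype=float), (8, 1))
        out = smooth_mean3x3(ImageRaster(img)).pixels
        np.testing.assert_allclose(out[1:-1, 1:-1], img[1:-1, 1:-1])

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            smooth_mean3x3(ImageRaster(np.ones((2, 5))))


def otsu_split_variances(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Independent oracle: between-class variance of every 256-bin split.

    Returns (bin_centers, variances) where variances[t] scores the split
    with background = bins 0..t, computed by explicit per-split summation.
    """
    counts, edges = np.histogram(data, bins=256)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = counts.sum()
    variances = np.full(255, -np.inf)
    for t in range(255):
        w0 = counts[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[: t + 1] * centers[: t + 1]).sum() / w0
        m1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / w1
        variances[t] = w0 * w1 * (m0 - m1) ** 2
    return centers, variances


def assert_otsu_optimal(data: np.ndarray) -> None:
    """Check otsu_binarize against the exhaustive oracle.

    The threshold behind the returned mask must achieve the maximal
    between-class variance; empty-bin plateaus make the optimal threshold
    non-unique, so ties (to 1e-9 relative) are accepted.
    """
    from skimage.filters import threshold_otsu

    mask = otsu_binarize(ImageRaster(data))
    centers, variances = otsu_split_variances(data)
    thr = threshold_otsu(data, nbins=256)
    np.testing.assert_array_equal(mask, data > thr)  # mask convention
    split = int(np.argmin(np.abs(centers - thr)))
    best = variances.max()
    assert variances[split] >= best * (1 - 1e-9)


class TestOtsu:
    def test_two_level_image_splits_exactly(self):
        rng = np.random.default_rng(3)
        img = np.full(16, 10.0)
        bright = rng.choice(16, size=8, replace=False)
        img[bright] = 200.0
        img = img.reshape(4, 4)
        mask = otsu_binarize(ImageRaster(img))
        np.testing.assert_array_equal(mask, img == 200.0)

    def test_agrees_with_bruteforce_on_random_images(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            assert_otsu_optimal(rng.uniform(0, 1000, size=(16, 16)))

    def test_constant_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            mask = otsu_binarize(ImageRaster(np.full((8, 8), 5.0)))
        assert not mask.any()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        data = rng.integers(0, 2000, size=(16, 16)).astype(float)
        m1 = otsu_binarize(ImageRaster(data))
        m2 = otsu_binarize(ImageRaster(data * 2))
        np.testing.assert_array_equal(m1, m2)


class TestSmoothMaskBorders:
    def test_radius_zero_is_identity(self):
        mask = rasterize_disk(6).astype(bool)
        np.testing.assert_array_equal(smooth_mask_borders(mask, 0), mask)

    def test_spur_removed_disk_intact(self):
        mask = rasterize_disk(10).astype(bool)
        area = mask.sum()
        spur = mask.copy()
        spur[14, 25:28] = True  # 1-px spur sticking out to the right
        out = smooth_mask_borders(spur, 2)
        assert not out[14, 26]
        assert abs(int(out.sum()) - area) / area < 0.05

    def test_full_mask_invariant(self):
        mask = np.ones((20, 20), dtype=bool)
        np.testing.assert_array_equal(smooth_mask_borders(mask, 2), mask)


class TestWatershedSplit:
    def test_single_disk_one_label(self):
        mask = rasterize_disk(10).astype(bool)
        labels = watershed_split(mask, min_seed_depth=2.0)
        assert labels.max() == 1
        np.testing.assert_array_equal(labels > 0, mask)

    def test_two_overlapping_disks_split_into_two(self):
        lone_area = rasterize_disk(10).sum()
        mask = np.zeros((40, 56), dtype=bool)
        yy, xx = np.mgrid[:40, :56]
        mask |= (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        mask |= (yy - 20) ** 2 + (xx - 36) ** 2 <= 100
        labels = watershed_split(mask, min_seed_depth=2.0)
        assert labels.max() == 2
        for lab in (1, 2):
            area = (labels == lab).sum()
            assert abs(area - lone_area) / lone_area < 0.20

    def test_disjoint_disks_match_connected_components(self):
        from scipy import ndimage as ndi

        mask = np.zeros((30, 60), dtype=bool)
        yy, xx = np.mgrid[:30, :60]
        mask |= (yy - 15) ** 2 + (xx - 13) ** 2 <= 64
        mask |= (yy - 15) ** 2 + (xx - 45) ** 2 <= 64
        labels = watershed_split(mask, min_seed_depth=2.0)
        comps, n = ndi.label(mask, structure=np.ones((3, 3)))
        assert labels.max() == n == 2
        np.testing.assert_array_equal(labels > 0, mask)

    def test_empty_mask_gives_zero_labels(self):
        labels = watershed_split(np.zeros((10, 10), dtype=bool))
        assert labels.max() == 0

    def test_labels_stay_inside_mask(self):
        rng = np.random.default_rng(5)
        mask = rng.random((40, 40)) > 0.4
        labels = watershed_split(mask, min_seed_depth=1.0)
        assert not (labels[~mask] > 0).any()


def dilate_bruteforce(labeled: np.ndarray, radius: int) -> np.ndarray:
    """Oracle: per-pixel nearest-ROI search with lower-id tie-break."""
    out = labeled.copy()
    coords = {
        lab: np.argwhere(labeled == lab) for lab in range(1, labeled.max() + 1)
    }
    for r, c in np.argwhere(labeled == 0):
        best_lab, best_d = 0, radius + 1e-9
        for lab in sorted(coords):
            d = np.sqrt(((coords[lab] - (r, c)) ** 2).sum(axis=1)).min()
            if d < best_d:
                best_lab, best_d = lab, d
        if best_lab:
            out[r, c] = best_lab
    return out


class TestDilateLabels:
    def test_radius_zero_identity(self):
        labels = rasterize_disk(5)
        np.testing.assert_array_equal(dilate_labels(labels, 0), labels)

    def test_matches_bruteforce_oracle(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[3:6, 3:6] = 1
        labels[10:13, 9:12] = 2
        for radius in (1, 2, 3):
            np.testing.assert_array_equal(
                dilate_labels(labels, radius), dilate_bruteforce(labels, radius)
            )

    def test_disk_grows_to_larger_disk(self):
        labels = rasterize_disk(5, pad=4)
        grown = dilate_labels(labels, 2)
        # pixel within distance 2 of the disk <=> oracle says label 1
        np.testing.assert_array_equal(grown, dilate_bruteforce(labels, 2))
        assert grown.sum() > labels.sum()

    def test_close_labels_never_merge(self):
        labels = np.zeros((12, 20), dtype=int)
        labels[4:8, 3:8] = 1
        labels[4:8, 11:16] = 2  # 3 px gap
        grown = dilate_labels(labels, 3)
        assert set(np.unique(grown)) == {0, 1, 2}
        # every original pixel keeps its label (monotonicity)
        assert (grown[labels > 0] == labels[labels > 0]).all()
        # the contested middle column ties to the lower id
        assert grown[5, 9] == 1


class TestExtractRois:
    def test_empty_label_image(self):
        assert extract_rois(np.zeros((8, 8), dtype=int)) == []

    def test_square_roi_properties(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[2:5, 2:5] = 1
        (roi,) = extract_rois(labels)
        assert roi.area_px == 9
        assert roi.centroid == (3.0, 3.0)
        assert roi.bbox == (2, 2, 5, 5)
        assert not roi.touches_border

    def test_border_pixel_sets_flag(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[0, 5] = 1
        labels[1, 5] = 1
        (roi,) = extract_rois(labels)
        assert roi.touches_border

    def test_ids_in_raster_scan_order(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[6:8, 1:3] = 1  # later in raster order despite lower input label
        labels[1:3, 6:8] = 2
        rois = extract_rois(labels)
        assert [r.acinus_id for r in rois] == [1, 2]
        assert rois[0].bbox[0] == 1  # first ROI is the topmost one
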