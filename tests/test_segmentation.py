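import numpy as np
import pytest
from scipy import ndimage as ndi

from duospot.segmentation import (
    AREA_CUTOFF,
    NucleusParams,
    adaptive_mask,
    detect_rois,
    expand_cells,
    li_threshold,
    segment_nuclei,
)


def brute_force_li(image):
    """Independent oracle: plain-python exhaustive cross-entropy minimization.

    Tests every candidate level; reports the midpoint between the optimal
    level and the next one (threshold strictly between the two classes).
    """
    values = np.asarray(image, float).ravel()
    candidates = sorted(set(values.tolist()))
    best_i, best_eta = None, np.inf
    for i, t in enumerate(candidates[:-1]):
        back = values[values <= t]
        fore = values[values > t]
        eta = 0.0
        sb = back.sum()
        if sb > 0:
            eta -= sb * np.log(back.mean())
        sf = fore.sum()
        if sf > 0:
            eta -= sf * np.log(fore.mean())
        if eta < best_eta:
            best_eta, best_i = eta, i
    return (candidates[best_i] + candidates[best_i + 1]) / 2


class TestLiThreshold:
    def test_bimodal_separates(self):
        img = np.concatenate([np.full(50, 10.0), np.full(50, 100.0)]).reshape(10, 10)
        t = li_threshold(img)
        assert 10 < t < 100

    def test_equals_brute_force_on_random_8bit(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            img = rng.integers(0, 256, size=(24, 24)).astype(float)
            assert li_threshold(img) == brute_force_li(img)

    def test_constant_image_returns_constant(self):
        img = np.full((8, 8), 7.0)
        t = li_threshold(img)
        assert t == 7.0
        assert not (img > t).any()  # empty foreground


class TestAdaptiveMask:
    def test_uniform_illumination_matches_global(self):
        tile = np.full((32, 32), 10.0)
        tile[8:12, 8:12] = 100.0
        img = np.tile(tile, (4, 8))
        global_mask = img > li_threshold(img)
        assert np.array_equal(adaptive_mask(img, window=32), global_mask)

    def test_shading_fixture_recovers_spot_missed_globally(self):
        h, w = 128, 256
        yy, xx = np.mgrid[0:h, 0:w]
        img = np.linspace(0, 2000, w)[None, :] * np.ones((h, 1))
        for cx in (40, 216):
            img += 300 * np.exp(-((yy - 64) ** 2 + (xx - cx) ** 2) / (2 * 1.5**2))
        # global threshold misses the dim-side spot by construction
        assert img[64, 40] < li_threshold(img)
        assert img[64, 216] > li_threshold(img)
        mask = adaptive_mask(img, window=32)
        assert mask[64, 40] and mask[64, 216]

    def test_lower_bound_above_max_empties_mask(self):
        img = np.random.default_rng(0).random((64, 64)) * 100
        assert not adaptive_mask(img, window=16, lower_bound=1e6).any()

    def test_oversized_window_falls_back_to_global(self):
        tile = np.full((32, 32), 10.0)
        tile[8:12, 8:12] = 100.0
        mask = adaptive_mask(tile, window=64)
        assert np.array_equal(mask, tile > li_threshold(tile))

    def test_small_window_rejected(self):
        with pytest.raises(ValueError):
            adaptive_mask(np.zeros((32, 32)), window=4)

    def test_correction_scales_threshold(self):
        img = np.full((64, 64), 10.0)
        img[30:34, 30:34] = 100.0
        strict = adaptive_mask(img, window=64, correction=10.0)
        lax = adaptive_mask(img, window=64, correction=1.0)
        assert strict.sum() <= lax.sum()


def _disk_image(shape, centers, radius, amplitude):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for (y, x), amp in zip(centers, amplitude):
        img += amp * (np.hypot(yy - y, xx - x) < radius)
    return img


class TestDetectRois:
    def test_single_blob_single_box(self):
        binned = _disk_image((64, 64), [(32, 32)], 5, [1000.0])
        rois = detect_rois(binned, bin_factor=8)
        assert len(rois) == 1
        r0, c0, r1, c1 = rois[0].bounds
        assert r0 <= 32 * 8 <= r1 and c0 <= 32 * 8 <= c1

    def test_blank_image_gives_no_rois(self):
        assert detect_rois(np.zeros((64, 64)), bin_factor=8) == []

    def test_neighbor_nuclei_excluded_from_roi_mask(self):
        binned = _disk_image((64, 64), [(30, 28), (30, 40)], 4, [1000.0, 1000.0])
        rois = detect_rois(binned, bin_factor=8, margin=60)
        assert len(rois) == 2
        # each ROI's mask covers its own nucleus center but not the neighbor's
        for roi, own, other in zip(rois, [(30, 28), (30, 40)], [(30, 40), (30, 28)]):
            r0, c0, _, _ = roi.bounds
            oy, ox = own[0] * 8 - r0, own[1] * 8 - c0
            ny, nx = other[0] * 8 - r0, other[1] * 8 - c0
            assert roi.roi_mask[oy, ox]
            if 0 <= ny < roi.roi_mask.shape[0] and 0 <= nx < roi.roi_mask.shape[1]:
                assert not roi.roi_mask[ny, nx]

    def test_bounds_clipped_to_image(self):
        binned = _disk_image((64, 64), [(2, 2)], 3, [1000.0])
        rois = detect_rois(binned, bin_factor=8, margin=100)
        r0, c0, r1, c1 = rois[0].bounds
        assert r0 >= 0 and c0 >= 0 and r1 <= 512 and c1 <= 512


class TestSegmentNuclei:
    def test_single_bright_disk(self):
        img = _disk_image((128, 128), [(64, 64)], 15, [3000.0])
        labels = segment_nuclei(img, NucleusParams(min_diameter=10, max_diameter=60))
        assert labels.max() == 1

    def test_two_pass_recovers_dim_nucleus(self):
        yy, xx = np.mgrid[0:200, 0:200]
        img = 3000.0 * (np.hypot(yy - 60, xx - 60) < 20)
        img += 150.0 * (np.hypot(yy - 140, xx - 140) < 18)
        img += 40.0 * np.exp(-((yy - 100) ** 2 + (xx - 100) ** 2) / (2 * 80**2))
        # a single global pass finds only the bright nucleus by construction
        smoothed = ndi.gaussian_filter(img, 2)
        single = ndi.label(smoothed > li_threshold(smoothed))[1]
        assert single == 1
        labels = segment_nuclei(img, NucleusParams(min_diameter=10, max_diameter=80))
        assert labels.max() == 2

    def test_small_object_filtered(self):
        img = _disk_image((64, 64), [(32, 32)], 3, [3000.0])
        labels = segment_nuclei(img, NucleusParams(min_diameter=16, max_diameter=60))
        assert labels.max() == 0

    def test_centroid_accuracy(self):
        img = _disk_image((128, 128), [(40, 50), (90, 80)], 12, [3000.0, 2500.0])
        labels = segment_nuclei(img, NucleusParams(min_diameter=10, max_diameter=60))
        assert labels.max() == 2
        centroids = ndi.center_of_mass(np.ones_like(labels), labels, [1, 2])
        found = sorted(centroids)
        for (fy, fx), (ty, tx) in zip(found, [(40, 50), (90, 80)]):
            assert np.hypot(fy - ty, fx - tx) <= 2.0


class TestExpandCells:
    def _nucleus(self, shape, center, radius):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return (np.hypot(yy - center[0], xx - center[1]) < radius).astype(np.int32)

    def test_small_nucleus_expands_12(self):
        nuclei = self._nucleus((128, 128), (64, 64), 25)  # area ~1963 < 2800
        assert int(nuclei.sum()) < AREA_CUTOFF
        cells = expand_cells(nuclei)
        # oracle: expansion by 12 px equals EDT distance <= 12 from the nucleus
        dist = ndi.distance_transform_edt(nuclei == 0)
        assert np.array_equal(cells.labels > 0, dist <= 12)
        assert cells.expansion_px[1] == 12

    def test_large_nucleus_expands_32(self):
        nuclei = self._nucleus((160, 160), (80, 80), 31)  # area ~3019 >= 2800
        assert int(nuclei.sum()) >= AREA_CUTOFF
        cells = expand_cells(nuclei)
        dist = ndi.distance_transform_edt(nuclei == 0)
        assert np.array_equal(cells.labels > 0, dist <= 32)
        assert cells.expansion_px[1] == 32

    def test_exact_cutoff_takes_large_budget(self):
        nuclei = np.zeros((200, 200), np.int32)
        nuclei[50:100, 50:106] = 1  # exactly 2800 px
        assert int(nuclei.sum()) == AREA_CUTOFF
        assert expand_cells(nuclei).expansion_px[1] == 32

    def test_close_nuclei_stay_disjoint(self):
        nuclei = self._nucleus((128, 128), (64, 50), 8)
        nuclei += 2 * self._nucleus((128, 128), (64, 76), 8)  # 10 px gap
        cells = expand_cells(nuclei)
        assert set(np.unique(cells.labels)) == {0, 1, 2}
        # nucleus subset of cell, no overlap
        for lab in (1, 2):
            assert ((nuclei == lab) <= (cells.labels == lab)).all()

    def test_boundary_distance_within_budget(self):
        nuclei = self._nucleus((128, 128), (64, 64), 20)
        cells = expand_cells(nuclei)
        dist = ndi.distance_transform_edt(nuclei == 0)
        assert dist[cells.labels == 1].max() <= cells.expansion_px[1]

    def test_empty_input(self):
        cells = expand_cells(np.zeros((16, 16), np.int32))
        assert cells.labels.max() == 0
        assert cells.expansion_px == {}
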