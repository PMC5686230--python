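"""Otsu thresholds, adaptive thresholding, and gland/nucleus segmentation."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import ndimage as ndi

from wsicyto.segmentation import (SegmentationError, SegmentationParams,
                                  adaptive_otsu, image_histogram, marker_mask,
                                  otsu_level, segment_glands, segment_nuclei)


def brute_force_otsu(hist):
    """Independent oracle: exhaustive between-class-variance maximization
    with exact rational arithmetic, ties toward the lower level."""
    hist = [int(c) for c in hist]
    total = sum(hist)
    best_t, best_v = None, Fraction(-1)
    for t in range(256):
        w0 = sum(hist[:t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = Fraction(sum(i * hist[i] for i in range(t + 1)), w0)
        mu1 = Fraction(sum(i * hist[i] for i in range(t + 1, 256)), w1)
        v = Fraction(w0, total) * Fraction(w1, total) * (mu0 - mu1) ** 2
        if v > best_v:
            best_v, best_t = v, t
    return best_t


class TestOtsuLevel:
    def test_two_spikes_are_separated(self):
        hist = np.zeros(256, dtype=int)
        hist[50] = 100
        hist[200] = 100
        level = otsu_level(hist)
        assert not level.degenerate
        assert 50 <= level.level < 200  # mask = pixel > level splits the spikes

    def test_constant_image_flags_degeneracy(self):
        hist = np.zeros(256, dtype=int)
        hist[77] = 1234
        level = otsu_level(hist)
        assert level.degenerate
        assert level.level == 77

    def test_matches_brute_force_on_random_histograms(self, rng):
        for _ in range(100):
            hist = rng.integers(0, 50, size=256)
            # random bimodal mixtures too
            a, b = rng.integers(0, 100), rng.integers(120, 255)
            hist[a] += int(rng.integers(100, 500))
            hist[b] += int(rng.integers(100, 500))
            assert otsu_level(hist).level == brute_force_otsu(hist)

    def test_all_zero_histogram_rejected(self):
        with pytest.raises(SegmentationError):
            otsu_level(np.zeros(256, dtype=int))


class TestAdaptiveOtsu:
    def test_uniform_bimodal_image_reduces_to_global(self, rng):
        img = np.where(rng.random((400, 400)) < 0.3, 200, 20).astype(np.uint8)
        glob = otsu_level(image_histogram(img)).level
        thr = adaptive_otsu(img, window=100)
        assert np.all(np.abs(thr - glob) <= 1.0)

    def test_background_ramp_defeats_global_but_not_adaptive(self):
        # linear background ramp 0..160 plus constant-offset (+60) objects:
        # the global threshold provably splits the ramp instead of the
        # objects, while the local threshold map recovers all of them
        h, w = 400, 400
        ramp = np.linspace(0, 160, w)[None, :] * np.ones((h, 1))
        img = ramp.copy()
        # keep objects inside the interpolable region (away from the
        # edge-clamped threshold margin)
        centers = [(r, c) for r in range(50, h, 100) for c in (50, 150, 250)]
        for r, c in centers:
            img[r - 8:r + 8, c - 8:c + 8] += 60
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

        def found(mask):
            labels, _ = ndi.label(mask)
            return sum(1 for r, c in centers if labels[r, c] > 0
                       and (labels == labels[r, c]).sum() < 1000)

        glob = otsu_level(image_histogram(img)).level
        thr = adaptive_otsu(img, window=100)
        assert found(img > thr) == len(centers)
        assert found(img > glob) < len(centers)

    def test_constant_image_gives_degenerate_map(self):
        img = np.full((200, 200), 99, dtype=np.uint8)
        thr = adaptive_otsu(img, window=64)
        assert np.all(thr == 99.0)
        assert not np.any(img > thr)

    def test_window_larger_than_image_falls_back_to_global(self, rng):
        img = np.where(rng.random((64, 64)) < 0.3, 200, 20).astype(np.uint8)
        glob = otsu_level(image_histogram(img)).level
        assert np.all(adaptive_otsu(img, window=128) == float(glob))

    def test_too_small_window_rejected(self):
        with pytest.raises(SegmentationError):
            adaptive_otsu(np.zeros((64, 64), np.uint8), window=16)


def _ellipse(canvas, cy, cx, a, b, value=180):
    yy, xx = np.mgrid[0:canvas.shape[0], 0:canvas.shape[1]]
    canvas[((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0] = value
    return canvas


class TestSegmentGlands:
    def test_two_overlapping_ellipses_are_split(self):
        img = np.zeros((400, 600), dtype=np.uint8)
        _ellipse(img, 200, 200, 100, 80)
        _ellipse(img, 200, 350, 100, 80)  # centres 1.5 major axes apart
        labels = segment_glands(img, SegmentationParams(
            gland_threshold_mode="global", gland_seed_min_distance=60))
        assert labels.max() == 2
        assert labels[200, 160] != labels[200, 390]

    def test_blank_channel_yields_no_glands(self):
        labels = segment_glands(np.zeros((256, 256), dtype=np.uint8))
        assert labels.max() == 0

    def test_lumina_are_filled(self):
        img = np.zeros((300, 300), dtype=np.uint8)
        _ellipse(img, 150, 150, 100, 90)
        _ellipse(img, 150, 150, 45, 40, value=0)  # lumen
        labels = segment_glands(img)
        assert labels.max() == 1
        assert labels[150, 150] == 1  # luminal pixel counts as inside

    def test_planted_glands_recovered_with_good_overlap(self, small_immune_slide):
        cfg, fl, bf, truth = small_immune_slide
        labels = segment_glands(fl["pan_epi"].pixels, SegmentationParams(
            gland_threshold_mode="global"))
        assert labels.max() == len(truth.glands)
        # per-gland IoU against the planted (filled) ellipse
        yy, xx = np.mgrid[0:labels.shape[0], 0:labels.shape[1]]
        for _, g in truth.glands.iterrows():
            ca, sa = np.cos(g.angle_rad), np.sin(g.angle_rad)
            u = ca * (xx - g.x_px) + sa * (yy - g.y_px)
            v = -sa * (xx - g.x_px) + ca * (yy - g.y_px)
            planted = (u / g.a_px) ** 2 + (v / g.b_px) ** 2 <= 1.0
            lab = labels[int(g.y_px), int(g.x_px)]
            assert lab > 0
            detected = labels == lab
            iou = (planted & detected).sum() / (planted | detected).sum()
            assert iou >= 0.7


def _gaussian_blob(canvas, cy, cx, sigma, amp):
    yy, xx = np.mgrid[0:canvas.shape[0], 0:canvas.shape[1]]
    canvas += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
    return canvas


class TestSegmentNuclei:
    def test_single_blob_of_valid_diameter_found(self):
        img = np.zeros((200, 200))
        _gaussian_blob(img, 100, 100, 10, 220)  # thresholded diameter ~40 px
        labels = segment_nuclei(np.clip(img, 0, 255).astype(np.uint8))
        assert labels.max() == 1

    def test_touching_pair_declumped(self):
        img = np.zeros((200, 200))
        _gaussian_blob(img, 100, 85, 9, 220)
        _gaussian_blob(img, 100, 115, 9, 220)  # centres 30 px apart
        labels = segment_nuclei(np.clip(img, 0, 255).astype(np.uint8))
        assert labels.max() == 2
        assert labels[100, 80] != labels[100, 120]

    def test_undersized_object_discarded(self):
        img = np.zeros((200, 200))
        _gaussian_blob(img, 100, 100, 2.5, 220)  # diameter ~10 px
        labels = segment_nuclei(np.clip(img, 0, 255).astype(np.uint8))
        assert labels.max() == 0

    def test_label_ids_contiguous_and_disjoint(self, small_immune_slide):
        cfg, fl, bf, truth = small_immune_slide
        labels = segment_nuclei(fl["dapi"].pixels)
        ids = np.unique(labels)
        assert ids[0] == 0
        assert np.array_equal(ids[1:], np.arange(1, labels.max() + 1))

    def test_nontouching_planted_cells_recovered_exactly(self, rng):
        img = np.zeros((600, 600))
        pts = []
        while len(pts) < 40:
            p = rng.uniform(40, 560, 2)
            if all(np.hypot(*(p - q)) > 60 for q in pts):
                pts.append(p)
        for r, c in pts:
            _gaussian_blob(img, r, c, 9, 225)
        labels = segment_nuclei(np.clip(img, 0, 255).astype(np.uint8))
        assert labels.max() == len(pts)


class TestMarkerMask:
    def test_bimodal_channel_mask_covers_high_mode(self, rng):
        img = np.where(rng.random((200, 200)) < 0.2, 210, 15).astype(np.uint8)
        level = otsu_level(image_histogram(img)).level
        mask = marker_mask(img)
        assert np.array_equal(mask, img > level)
        assert mask[img == 210].all() and not mask[img == 15].any()

    def test_blank_channel_is_all_false(self):
        assert not marker_mask(np.full((64, 64), 7, np.uint8)).any()

    def test_planted_leukocyte_footprints_recovered(self, small_immune_slide):
        cfg, fl, bf, truth = small_immune_slide
        mask = marker_mask(fl["cd45"].pixels)
        leuk = truth.cells[truth.cells.true_class.isin(
            ["treg", "th", "te", "leukocyte_other"])]
        hits = mask[leuk.y_px.round().astype(int), leuk.x_px.round().astype(int)]
        assert hits.mean() >= 0.9
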