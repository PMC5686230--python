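"""Keypoint detection, matching, robust affine estimation, registration."""

import numpy as np
import pytest

from wsicyto.registration import (AffineTransform, Keypoint,
                                  RegistrationError, detect_and_describe,
                                  estimate_affine, least_squares_affine,
                                  match_descriptors, register_modalities)
from wsicyto.stains import deconvolve
from wsicyto.synthetic import PlantedTransform, generate_slide, immune_config
from wsicyto.wsi_io import ChannelImage


def _blob_image(centers, shape=(300, 300), sigma=6.0, amp=200.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for r, c in centers:
        img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma ** 2))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


class TestDetectAndDescribe:
    def test_uniform_image_has_no_keypoints(self):
        assert detect_and_describe(np.full((128, 128), 60, np.uint8)) == []

    def test_blobs_detected_near_their_centres(self, rng):
        centers = [(r, c) for r in range(50, 300, 60)
                   for c in range(50, 300, 60)][:10]
        img = _blob_image(centers)
        kps = detect_and_describe(img)
        assert len(kps) >= len(centers)
        pos = np.array([kp.position for kp in kps])
        for r, c in centers:
            d = np.min(np.hypot(pos[:, 0] - r, pos[:, 1] - c))
            assert d <= 2.0

    def test_detection_is_deterministic(self, rng):
        img = _blob_image([(80, 90), (150, 200), (220, 60)])
        a = detect_and_describe(img)
        b = detect_and_describe(img)
        assert len(a) == len(b)
        for ka, kb in zip(a, b):
            assert ka.position == kb.position
            assert np.array_equal(ka.descriptor, kb.descriptor)

    def test_tiny_image_rejected(self):
        with pytest.raises(RegistrationError):
            detect_and_describe(np.zeros((8, 8), np.uint8))


class TestMatchDescriptors:
    def _keypoints(self, descriptors):
        return [Keypoint((0.0, float(i)), 2.0, 0.0, np.asarray(d, float))
                for i, d in enumerate(descriptors)]

    def test_identical_sets_match_one_to_one(self, rng):
        desc = rng.normal(size=(12, 16))
        desc /= np.linalg.norm(desc, axis=1, keepdims=True)
        kps = self._keypoints(desc)
        matches = match_descriptors(kps, kps, max_ratio=1.0)
        assert sorted(matches) == [(i, i) for i in range(12)]

    def test_impostor_with_orthogonal_descriptor_unmatched(self, rng):
        base = np.eye(6)[:5]
        a = self._keypoints(base)
        impostor = np.eye(6)[5]
        b = self._keypoints(np.vstack([base, impostor]))
        matches = match_descriptors(a, b)
        assert all(j != 5 for _, j in matches)

    def test_empty_inputs_give_empty_matches(self):
        assert match_descriptors([], []) == []

    def test_mismatched_descriptor_lengths_rejected(self, rng):
        a = self._keypoints(np.ones((2, 8)))
        b = self._keypoints(np.ones((2, 9)))
        with pytest.raises(ValueError):
            match_descriptors(a, b)


class TestEstimateAffine:
    def test_identity_recovered(self, rng):
        pts = rng.uniform(0, 500, size=(40, 2))
        est = estimate_affine(pts, pts)
        assert np.allclose(est.transform.matrix, np.eye(3), atol=1e-6)

    def test_translation_recovered_despite_gross_outliers(self, rng):
        src = rng.uniform(0, 500, size=(60, 2))
        dst = src + np.array([12.0, -7.0])
        n_out = 18  # 30 % gross outliers
        dst[:n_out] = rng.uniform(0, 500, size=(n_out, 2))
        est = estimate_affine(src, dst, seed=0)
        assert np.allclose(est.transform.translation, [12.0, -7.0], atol=0.5)
        assert est.inliers.sum() >= 60 - n_out

    def test_rotation_and_scale_recovered(self, rng):
        theta = np.radians(5.0)
        scale = 1.02
        rot = scale * np.array([[np.cos(theta), -np.sin(theta)],
                                [np.sin(theta), np.cos(theta)]])
        src = rng.uniform(0, 500, size=(50, 2))
        dst = src @ rot.T + [5.0, 9.0]
        est = estimate_affine(src, dst, seed=0)
        assert est.transform.rotation_deg == pytest.approx(5.0, rel=1e-2)
        assert est.transform.scale == pytest.approx(1.02, rel=1e-2)

    def test_refit_equals_normal_equations_oracle(self, rng):
        src = rng.uniform(0, 100, size=(25, 2))
        truth = np.array([[1.01, 0.03, 4.0], [-0.02, 0.99, -7.0], [0, 0, 1.0]])
        dst = (np.hstack([src, np.ones((25, 1))]) @ truth.T)[:, :2]
        dst += rng.normal(0, 0.1, dst.shape)
        fit = least_squares_affine(src, dst)
        # independent oracle: explicit normal equations
        a = np.hstack([src, np.ones((25, 1))])
        coef = np.linalg.solve(a.T @ a, a.T @ dst)
        oracle = np.eye(3)
        oracle[:2, :2] = coef[:2].T
        oracle[:2, 2] = coef[2]
        assert np.allclose(fit.matrix, oracle, atol=1e-9)

    def test_too_few_matches_fail_distinctly(self, rng):
        pts = rng.uniform(0, 10, size=(2, 2))
        with pytest.raises(RegistrationError):
            estimate_affine(pts, pts)


class TestAffineTransform:
    def test_inverse_composes_to_identity(self, rng):
        m = np.eye(3)
        m[:2, :2] = rng.normal(0, 1, (2, 2)) + np.eye(2) * 2
        m[:2, 2] = rng.normal(0, 10, 2)
        t = AffineTransform(m, 0.64)
        assert np.allclose(t.compose(t.inverse).matrix, np.eye(3), atol=1e-9)

    def test_json_roundtrip(self, tmp_path):
        t = AffineTransform(np.array([[1.0, 0.1, 3.0], [-0.1, 1.0, -2.0],
                                      [0, 0, 1.0]]), 0.64)
        path = tmp_path / "t.json"
        t.to_json(path)
        back = AffineTransform.from_json(path)
        assert np.allclose(back.matrix, t.matrix)
        assert back.resolution == 0.64

    def test_singular_linear_part_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1.0]]))


@pytest.fixture(scope="module")
def registered_pair():
    cfg = immune_config(
        image_height_px=1024, image_width_px=1024, rng_seed=21,
        gland_axes=(60, 120),
        planted_transform=PlantedTransform(rotation_deg=6.0, scale=1.015,
                                           translation_um=(28.0, -12.0)))
    fl, bf, truth = generate_slide(cfg)
    conc = deconvolve(bf, cfg.stain_matrix, downscale=1)
    haem = conc["haematoxylin"]
    haem8 = np.clip(np.rint(haem * 255.0 / np.percentile(haem, 99.9)),
                    0, 255).astype(np.uint8)
    reg = register_modalities(
        ChannelImage(haem8, cfg.bf_resolution, "haematoxylin"),
        fl["dapi"], seed=0)
    return cfg, truth, reg


class TestRegisterModalities:
    def test_planted_transform_recovered_within_one_pixel_rms(
            self, registered_pair, rng):
        cfg, truth, reg = registered_pair
        planted = truth.transform.as_affine(0.64, 0.64)
        control = rng.uniform(100, 900, size=(200, 2)) * cfg.fl_resolution / 0.64
        err = reg.transform.apply(control) - planted.apply(control)
        rms = float(np.sqrt(np.mean(np.sum(err ** 2, axis=1))))
        assert rms <= 1.0

    def test_output_grid_resolution_defaults_to_0_64(self, registered_pair):
        _, _, reg = registered_pair
        assert reg.transform.resolution == 0.64

    def test_identical_modalities_register_to_identity(self):
        cfg = immune_config(image_height_px=768, image_width_px=768,
                            gland_axes=(60, 100), rng_seed=5)
        fl, _, _ = generate_slide(cfg)
        dapi = fl["dapi"]
        reg = register_modalities(dapi, dapi, work_res_reference=1.76,
                                  work_res_moving=1.76, seed=0)
        control = np.array([[0.0, 0.0], [700.0, 0.0], [0.0, 700.0],
                            [700.0, 700.0]])
        err = reg.transform.apply(control) - control
        assert np.max(np.abs(err)) < 0.5


def test_resampling_preserves_mean_intensity_for_smooth_images(rng):
    from scipy import ndimage as ndi

    from wsicyto.registration import rescale_channel
    img = ndi.gaussian_filter(rng.uniform(40, 215, (512, 512)), 12)
    chan = ChannelImage(np.clip(np.rint(img), 0, 255).astype(np.uint8),
                        0.64, "x")
    out = rescale_channel(chan, 1.76)
    assert out.pixels.mean() == pytest.approx(chan.pixels.mean(), rel=0.02)
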