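"""Preprocessing: flat-field, median filter, registration, crop, normalize."""

import numpy as np
import pytest

from mouseview.preprocess import (
    Homography,
    RawCapture,
    SceneMetadata,
    ScenePair,
    correct_vignetting,
    crop,
    estimate_projective,
    median3x3,
    normalize_minmax,
    register_pair,
    relative_intensity_profiles,
)
from mouseview.synthetic import (
    MAX_DN,
    SyntheticSceneParams,
    make_control_points,
    make_scene_pair,
)


def _pair(uv, green, **kw):
    meta = SceneMetadata(stem="t", elevation="up")
    return ScenePair(uv=uv, green=green, metadata=meta, **kw)


class TestVignetting:
    def test_uniform_reference_is_identity(self, rng):
        raw = rng.integers(0, 4096, (64, 64)).astype(float)
        np.testing.assert_allclose(
            correct_vignetting(raw, np.full((64, 64), 1000.0)), raw
        )

    def test_raw_equals_reference_gives_constant(self, rng):
        ref = rng.uniform(100, 4000, (32, 32))
        out = correct_vignetting(ref, ref)
        np.testing.assert_allclose(out, ref.max())

    def test_round_trip_identity(self, rng):
        raw = rng.uniform(0, 4095, (32, 32))
        ref = rng.uniform(100, 4000, (32, 32))
        corrected = correct_vignetting(raw, ref)
        np.testing.assert_allclose(corrected * ref / ref.max(), raw, rtol=1e-12)

    def test_synthetic_vignette_recovery_within_one_dn(self):
        p = SyntheticSceneParams(
            height_px=96, width_px=96, intensity_mode="skewed_ground",
            vignette_strength=0.4, sp_noise_fraction=0.0, seed=4,
        )
        raw_uv, _, ref, truth = make_scene_pair(p)
        corrected = correct_vignetting(raw_uv, ref)
        gain = MAX_DN * 0.9 * (p.exposure_s / 0.01)
        # quantization loses < 1 DN before the correction divides by the
        # vignette, so the recovered image is within 1/min(v) DN of clean
        bound = 1.0 / truth.vignette_field.min()
        assert np.abs(corrected - truth.clean_uv * gain).max() <= bound

    def test_zero_reference_pixels_reported(self):
        ref = np.ones((8, 8))
        ref[2, 2] = 0.0
        ref[3, 3] = 0.0
        with pytest.raises(ValueError, match="2 non-positive"):
            correct_vignetting(np.ones((8, 8)), ref)


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((16, 16), 7.0)
        np.testing.assert_array_equal(median3x3(img), img)

    def test_impulse_removed(self):
        img = np.zeros((16, 16))
        img[8, 8] = 4095.0
        assert np.all(median3x3(img)[1:-1, 1:-1] == 0)

    def test_matches_sort_and_pick_oracle(self, rng):
        img = rng.uniform(0, 4095, (16, 16))
        out = median3x3(img)
        for i in range(1, 15):
            for j in range(1, 15):
                window = sorted(img[i - 1 : i + 2, j - 1 : j + 2].ravel())
                assert out[i, j] == window[4]

    def test_idempotent_on_impulse_noise(self, rng):
        # piecewise-constant stripes (straight edges) plus impulse noise
        img = np.repeat(rng.integers(200, 3800, 6).astype(float), 16)[None, :]
        img = np.repeat(img, 96, axis=0)
        idx = rng.choice(img.size, 40, replace=False)
        img.flat[idx] = np.where(rng.random(40) < 0.5, 0, 4095)
        once = median3x3(img)
        twice = median3x3(once)
        assert (once != twice).mean() < 0.001


class TestHomographyEstimation:
    def test_identity_correspondences(self, rng):
        pts = rng.uniform(0, 100, (8, 2))
        h = estimate_projective(pts, pts)
        np.testing.assert_allclose(h.matrix, np.eye(3), atol=1e-9)

    def test_four_exact_points(self):
        H = np.array([[1.1, 0.02, 5.0], [-0.01, 0.95, -3.0], [1e-4, -2e-5, 1.0]])
        src = np.array([[10.0, 10.0], [90.0, 15.0], [85.0, 80.0], [12.0, 88.0]])
        ones = np.ones((4, 1))
        dst = (H @ np.hstack([src, ones]).T).T
        dst = dst[:, :2] / dst[:, 2:3]
        h = estimate_projective(src, dst)
        np.testing.assert_allclose(h.matrix, H / H[2, 2], atol=1e-8)
        assert h.reprojection_errors.max() < 1e-8

    def test_jittered_recovery_under_one_px(self):
        _, _, _, truth = make_scene_pair(
            SyntheticSceneParams(height_px=128, width_px=128, seed=6)
        )
        src, dst = make_control_points(truth, 12, jitter_px=0.5, seed=8)
        h = estimate_projective(src, dst)
        ones = np.ones((12, 1))
        true_dst = (truth.homography @ np.hstack([src, ones]).T).T
        true_dst = true_dst[:, :2] / true_dst[:, 2:3]
        err = np.linalg.norm(h.apply(src) - true_dst, axis=1)
        assert err.mean() < 1.0

    def test_too_few_points(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            estimate_projective(pts, pts)


class TestRegistration:
    def test_identity_unchanged(self, smooth_image):
        uv_reg, _, valid = register_pair(
            smooth_image, smooth_image, Homography.identity()
        )
        assert valid.all()
        np.testing.assert_allclose(uv_reg, smooth_image, atol=1e-9)

    def test_integer_translation_exact(self, smooth_image):
        # H maps uv (x, y) -> (x + 5, y + 3) in the green frame
        H = np.array([[1.0, 0.0, 5.0], [0.0, 1.0, 3.0], [0.0, 0.0, 1.0]])
        uv_reg, _, valid = register_pair(smooth_image, smooth_image, Homography(H))
        # output pixel (y, x) = uv(y - 3, x - 5) on the valid region
        np.testing.assert_allclose(
            uv_reg[3:, 5:], smooth_image[:-3, :-5], atol=1e-9
        )
        assert not valid[:3, :].any() and not valid[:, :5].any()

    def test_warp_round_trip(self):
        # low-curvature analytic image: bilinear error ~ |f''|/8 per px^2
        y, x = np.mgrid[0:96, 0:96]
        img = 2047.0 * (1.0 + np.cos(2 * np.pi * x / 192) * np.cos(2 * np.pi * y / 192))
        H = np.array([[1.01, 0.004, 1.5], [-0.003, 0.99, -1.0], [0.0, 0.0, 1.0]])
        fwd, _, v1 = register_pair(img, img, Homography(H))
        fwd = np.where(v1, fwd, 0.0)
        back, _, v2 = register_pair(fwd, fwd, Homography(np.linalg.inv(H)))
        core = v1 & v2
        core[:6, :] = core[-6:, :] = core[:, :6] = core[:, -6:] = False
        assert np.abs(back - img)[core].max() < 2.0

    def test_insufficient_overlap_rejected(self, smooth_image):
        H = np.array([[1.0, 0.0, 90.0], [0.0, 1.0, 90.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="overlap"):
            register_pair(smooth_image, smooth_image, Homography(H))


class TestCropAndNormalize:
    def test_full_frame_identity(self, smooth_image):
        pair = _pair(smooth_image, smooth_image)
        out = crop(pair, (0, 96, 0, 96))
        np.testing.assert_array_equal(out.uv, pair.uv)
        assert out.pixel_pitch_deg == pair.pixel_pitch_deg

    def test_angular_extent_of_341px_crop(self):
        img = np.zeros((400, 400))
        pair = _pair(img, img)
        out = crop(pair, (0, 341, 0, 341))
        v, h = out.angular_extent_deg()
        assert v == pytest.approx(2.046)
        assert h == pytest.approx(2.046)  # ~2.0 degrees as printed

    def test_crop_composition(self, smooth_image):
        pair = _pair(smooth_image, smooth_image)
        once = crop(crop(pair, (10, 90, 5, 95)), (5, 40, 10, 60))
        composed = crop(pair, (15, 50, 15, 65))
        np.testing.assert_array_equal(once.uv, composed.uv)

    def test_empty_rect_rejected(self, smooth_image):
        pair = _pair(smooth_image, smooth_image)
        with pytest.raises(ValueError):
            crop(pair, (50, 50, 0, 96))

    def test_normalize_range_and_flag(self, rng):
        img = rng.uniform(100, 4000, (64, 64))
        pair = _pair(img, img * 2 + 7)
        out = normalize_minmax(pair)
        for ch in (out.uv, out.green):
            assert ch.min() == 0.0 and ch.max() == 1.0
        assert out.normalized

    def test_affine_invariance(self, rng):
        img = rng.uniform(0, 1, (32, 32))
        a = normalize_minmax(_pair(img, img))
        b = normalize_minmax(_pair(3.5 * img + 100.0, img))
        np.testing.assert_allclose(a.uv, b.uv, atol=1e-12)

    def test_two_level_image(self):
        img = np.full((64, 64), 100.0)
        img[::2] = 4000.0
        out = normalize_minmax(_pair(img, img))
        assert set(np.unique(out.uv)) == {0.0, 1.0}

    def test_constant_channel_rejected(self):
        img = np.full((64, 64), 5.0)
        with pytest.raises(ValueError, match="constant"):
            normalize_minmax(_pair(img, np.arange(64.0 * 64).reshape(64, 64)))


class TestRelativeIntensityProfiles:
    def _capture(self, value, elevation, exposure=0.01, nd=0.0, shape=(64, 64)):
        meta = SceneMetadata(stem=f"{elevation}{value}", elevation=elevation,
                             exposure_s=exposure, nd_od=nd)
        img = np.full(shape, value, dtype=np.uint16)
        return RawCapture(img, "UV", meta)

    def test_single_uniform_image_flat_at_one(self):
        out = relative_intensity_profiles([self._capture(1000, "up")], "vertical")
        np.testing.assert_allclose(out["up"]["median"], 1.0)

    def test_exposure_correction_equalizes(self):
        # same radiance captured at 2x exposure -> 2x counts; correction undoes it
        caps = [
            self._capture(1000, "up", exposure=0.01),
            self._capture(2000, "up", exposure=0.02),
        ]
        out = relative_intensity_profiles(caps, "vertical")
        np.testing.assert_allclose(out["up"]["q25"], out["up"]["q75"], atol=1e-12)

    def test_nd_correction(self):
        caps = [
            self._capture(1000, "up", nd=0.0),
            self._capture(100, "up", nd=1.0),  # attenuated 10x by the filter
        ]
        out = relative_intensity_profiles(caps, "vertical")
        np.testing.assert_allclose(out["up"]["q25"], out["up"]["q75"], atol=1e-12)

    def test_category_means_preserved(self):
        caps = [self._capture(2000, "up"), self._capture(1000, "down")]
        out = relative_intensity_profiles(caps, "vertical")
        assert np.nanmedian(out["up"]["median"]) == pytest.approx(
            2 * np.nanmedian(out["down"]["median"])
        )

    def test_vertical_alignment_of_unequal_heights(self):
        caps = [
            self._capture(1000, "down", shape=(64, 64)),
            self._capture(1000, "down", shape=(100, 64)),
        ]
        out = relative_intensity_profiles(caps, "vertical")
        med = out["down"]["median"]
        assert med.size == 100
        assert np.isfinite(med[:64]).all()  # top-edge aligned
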