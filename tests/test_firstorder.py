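"""First-order statistics: histograms, LoG kernel/contrast, Weibull MLE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mouseview.firstorder import (
    contrast_weibull_per_scene,
    fit_weibull,
    intensity_histogram,
    local_contrast_map,
    log_kernel,
)
from mouseview.preprocess import SceneMetadata, ScenePair, normalize_minmax
from mouseview.synthetic import sample_weibull, spectral_field


class TestIntensityHistogram:
    def test_uniform_half_image(self):
        h = intensity_histogram(np.full((32, 32), 0.5))
        assert h.probabilities[50] == 1.0

    def test_two_point_mass(self):
        img = np.zeros((32, 32))
        img[:16] = 1.0
        h = intensity_histogram(img)
        assert h.probabilities[0] == 0.5
        assert h.probabilities[99] == 0.5  # final bin right-closed at 1.0

    def test_mass_conservation_random(self, rng):
        h = intensity_histogram(rng.random((64, 64)))
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="not normalized"):
            intensity_histogram(np.full((32, 32), 2.0))

    def test_mask_restricts_pixels(self):
        img = np.zeros((32, 32))
        img[0, 0] = 1.0
        mask = np.zeros_like(img, dtype=bool)
        mask[0, 0] = True
        h = intensity_histogram(img, mask)
        assert h.probabilities[99] == 1.0


class TestLoGKernel:
    @pytest.mark.parametrize("sigma", [5.0, 10.0, 40.0])
    def test_center_weight_before_adjustment(self, sigma):
        k = log_kernel(sigma)
        r = k.support_px // 2
        center = k.weights[r, r] + k.zero_sum_offset
        assert center == pytest.approx(1.0 / (np.pi * sigma**4), rel=1e-12)

    def test_sign_change_on_circle(self):
        sigma = 10.0
        k = log_kernel(sigma)
        r = k.support_px // 2
        raw = k.weights + k.zero_sum_offset
        # analytic root locus of the polynomial factor: x^2 + y^2 = 2 sigma^2
        inside = raw[r, r + int(np.floor(sigma * np.sqrt(2))) - 2]
        outside = raw[r, r + int(np.ceil(sigma * np.sqrt(2))) + 2]
        assert inside > 0 > outside

    def test_exact_zero_sum_and_symmetry(self):
        k = log_kernel(5.0)
        assert abs(k.weights.sum()) < 1e-3 * np.abs(k.weights).max()
        np.testing.assert_allclose(k.weights, np.rot90(k.weights), atol=1e-15)
        np.testing.assert_allclose(k.weights, k.weights[::-1, ::-1], atol=1e-15)

    def test_support_size(self):
        assert log_kernel(5.0).support_px == 31  # 2*floor(3*5)+1
        assert log_kernel(5.0).support_deg(0.006) == pytest.approx(0.18)
        assert log_kernel(40.0).support_deg(0.006) == pytest.approx(1.44)

    def test_sigma_below_one_rejected(self):
        with pytest.raises(ValueError):
            log_kernel(0.5)


class TestLocalContrastMap:
    def test_constant_image_zero(self):
        k = log_kernel(2.0)
        out = local_contrast_map(np.full((40, 40), 0.7), k)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_annihilates_linear_ramp(self):
        k = log_kernel(2.0)
        y, x = np.mgrid[0:40, 0:40]
        ramp = 0.3 + 0.01 * x + 0.005 * y
        out = local_contrast_map(ramp, k)
        assert np.abs(out).max() < 1e-10

    def test_impulse_response_is_kernel(self):
        # valid convolution with a centred impulse returns the flipped kernel
        k = log_kernel(2.0)
        n = k.support_px
        full = np.zeros((3 * n, 3 * n))
        full[3 * n // 2, 3 * n // 2] = 1.0
        resp = local_contrast_map(full, k)
        c = resp.shape[0] // 2
        np.testing.assert_allclose(
            resp[c - n // 2 : c + n // 2 + 1, c - n // 2 : c + n // 2 + 1],
            k.weights[::-1, ::-1],
            atol=1e-12,
        )

    def test_output_shape_and_small_image_error(self):
        k = log_kernel(2.0)
        out = local_contrast_map(np.zeros((30, 25)), k)
        assert out.shape == (30 - 13 + 1, 25 - 13 + 1)
        with pytest.raises(ValueError, match="smaller"):
            local_contrast_map(np.zeros((10, 10)), k)

    def test_scale_covariance_downsampling(self, rng):
        # sigma kernel on a 2x-downsampled field ~ 2 sigma kernel on original
        field = spectral_field((256, 256), 3.0, rng)
        big = local_contrast_map(field, log_kernel(8.0))[::2, ::2]
        small = local_contrast_map(field[::2, ::2], log_kernel(4.0))
        m = min(big.shape[0], small.shape[0]) - 4
        a = big[2 : m + 2, 2 : m + 2].ravel()
        b = small[2 : m + 2, 2 : m + 2].ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.9


class TestFitWeibull:
    def test_exponential_recovery(self):
        x = sample_weibull(1.0, 1.0, 100_000, seed=0)
        fit = fit_weibull(x)
        assert fit.beta_scale == pytest.approx(1.0, abs=0.02)
        assert fit.gamma_shape == pytest.approx(1.0, abs=0.02)

    def test_heavy_tail_recovery(self):
        x = sample_weibull(0.05, 0.8, 100_000, seed=1)
        fit = fit_weibull(x)
        assert fit.beta_scale == pytest.approx(0.05, rel=0.02)
        assert fit.gamma_shape == pytest.approx(0.8, rel=0.02)

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(c=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, c):
        x = sample_weibull(1.0, 1.5, 2000, seed=2)
        base = fit_weibull(x)
        scaled = fit_weibull(c * x)
        assert scaled.beta_scale == pytest.approx(c * base.beta_scale, rel=1e-6)
        assert scaled.gamma_shape == pytest.approx(base.gamma_shape, rel=1e-6)

    def test_printed_rate_conversion(self):
        fit = fit_weibull(sample_weibull(0.3, 1.2, 5000, seed=3))
        assert fit.printed_rate == pytest.approx(fit.beta_scale**-fit.gamma_shape)

    def test_matches_grid_search_oracle(self, rng):
        for trial in range(5):
            beta = float(rng.uniform(0.05, 2.0))
            gamma = float(rng.uniform(0.5, 3.0))
            x = sample_weibull(beta, gamma, 2000, seed=100 + trial)
            fit = fit_weibull(x)
            # independent maximizer: dense log-grid likelihood evaluation
            betas = np.geomspace(beta / 3, beta * 3, 200)
            gammas = np.geomspace(gamma / 3, gamma * 3, 200)
            logx_sum = np.log(x).sum()
            ll = np.empty((200, 200))
            for i, b in enumerate(betas):
                z = (x[None, :] / b) ** gammas[:, None]
                ll[i] = (
                    x.size * (np.log(gammas) - gammas * np.log(b))
                    + (gammas - 1) * logx_sum
                    - z.sum(axis=1)
                )
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            db = betas[1] / betas[0]
            dg = gammas[1] / gammas[0]
            assert betas[i] / fit.beta_scale == pytest.approx(1.0, abs=2 * (db - 1))
            assert gammas[j] / fit.gamma_shape == pytest.approx(1.0, abs=2 * (dg - 1))

    def test_zeros_dropped_and_counted(self):
        x = np.concatenate([sample_weibull(1.0, 1.0, 500, seed=4), np.zeros(17)])
        fit = fit_weibull(x)
        assert fit.n_zeros_dropped == 17
        assert fit.n_samples == 500

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match=">= 20"):
            fit_weibull(np.ones(5))
        with pytest.raises(ValueError, match="all values equal"):
            fit_weibull(np.ones(50))
        with pytest.raises(ValueError, match="non-negative"):
            fit_weibull(np.array([-1.0] * 30))


class TestPerScene:
    def _pair(self, uv, green):
        meta = SceneMetadata(stem="s", elevation="up")
        return normalize_minmax(ScenePair(uv=uv, green=green, metadata=meta))

    def test_identical_channels_identical_fits(self, rng):
        img = spectral_field((96, 96), 2.0, rng)
        fits = contrast_weibull_per_scene(self._pair(img, img.copy()), sigmas=(5,))
        assert fits[("UV", 5.0)].beta_scale == fits[("Green", 5.0)].beta_scale

    def test_normalization_invariance(self, rng):
        img = spectral_field((96, 96), 2.0, rng)
        f1 = contrast_weibull_per_scene(self._pair(img, img), sigmas=(5,))
        f2 = contrast_weibull_per_scene(self._pair(2000.0 * img + 55.0, img),
                                        sigmas=(5,))
        assert f1[("UV", 5.0)].beta_scale == pytest.approx(
            f2[("UV", 5.0)].beta_scale, rel=1e-9
        )

    def test_heavier_uv_tail_gives_smaller_gamma(self, rng):
        green = spectral_field((128, 128), 2.0, rng)
        uv = green**4  # sparse bright structure -> heavier contrast tail
        fits = contrast_weibull_per_scene(self._pair(uv, green), sigmas=(5,))
        assert fits[("UV", 5.0)].gamma_shape < fits[("Green", 5.0)].gamma_shape

    def test_unnormalized_pair_rejected(self, rng):
        img = spectral_field((96, 96), 2.0, rng)
        meta = SceneMetadata(stem="s", elevation="up")
        with pytest.raises(ValueError, match="normalized"):
            contrast_weibull_per_scene(
                ScenePair(uv=img, green=img, metadata=meta), sigmas=(5,)
            )
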