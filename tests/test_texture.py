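"""Texture feature bank: smoothing, roughness/waviness, SD filter,
Prewitt slope, depth compensation, ROI summaries."""

import numpy as np
import pytest

from octmargin import phantom as ph
from octmargin import texture as tx
from octmargin import report as rp


def brute_force_sd(image, w):
    """Independent sliding-window population-SD oracle (edge-repeating
    reflected borders via explicit padding)."""
    b = w // 2
    padded = np.pad(image, b, mode="symmetric")
    out = np.zeros_like(image, dtype=float)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            win = padded[i:i + w, j:j + w]
            out[i, j] = win.std()
    return out


class TestGaussianSmooth:
    def test_constant_preserved(self):
        img = np.full((20, 20), 3.7)
        assert np.allclose(tx.gaussian_smooth(img, 2.0), 3.7)

    def test_impulse_center_value(self):
        # center of the discretized normalized kernel, computed by an
        # explicit sampled-kernel sum
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = tx.gaussian_smooth(img, 2.0)
        xx = np.arange(-20, 21)
        k1 = np.exp(-0.5 * (xx / 2.0) ** 2)
        k1 /= k1.sum()
        expected = k1[20] ** 2  # separable kernel center
        assert out[20, 20] == pytest.approx(expected, rel=1e-3)

    def test_variance_reduction(self, rng):
        img = rng.standard_normal((64, 64))
        assert tx.gaussian_smooth(img, 3.0).var() < img.var()

    def test_rejects_bad_sigma(self):
        with pytest.raises(ValueError):
            tx.gaussian_smooth(np.zeros((5, 5)), 0.0)


class TestRoughnessDecompose:
    def test_constant_has_zero_roughness(self):
        wav, rough = tx.roughness_decompose(np.full((30, 30), 2.0), 2.0, 16.0)
        assert np.allclose(rough, 0.0, atol=1e-12)

    def test_low_frequency_goes_to_waviness(self):
        # a sinusoid with period much larger than sigma_waviness passes
        # into the waviness map almost untouched
        x = np.arange(256)
        img = np.tile(np.sin(2 * np.pi * x / 200.0), (32, 1))
        wav, rough = tx.roughness_decompose(img, 1.0, 8.0)
        interior = rough[:, 32:-32]
        assert np.abs(interior).max() < 0.10 * 1.0

    def test_checkerboard_goes_to_roughness(self):
        img = np.indices((64, 64)).sum(axis=0) % 2.0
        wav, rough = tx.roughness_decompose(img, 0.5, 8.0)
        # waviness ~ global mean; roughness carries the oscillation that
        # survives the sigma_smooth filter
        assert np.allclose(wav[8:-8, 8:-8], 0.5, atol=0.01)
        smoothed = tx.gaussian_smooth(img, 0.5)
        assert np.allclose(rough, smoothed - wav)
        assert rough[8:-8, 8:-8].std() > 0.05

    def test_exact_reconstruction(self, rng):
        img = rng.standard_normal((48, 48))
        wav, rough = tx.roughness_decompose(img, 2.0, 16.0)
        assert np.allclose(wav + rough, tx.gaussian_smooth(img, 2.0))

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            tx.roughness_decompose(np.zeros((10, 10)), 4.0, 2.0)


class TestRoughnessSd:
    def test_constant_is_zero(self):
        assert np.allclose(tx.roughness_sd(np.full((20, 20), 5.0), 5), 0.0)

    def test_matches_brute_force_oracle(self, rng):
        img = rng.standard_normal((32, 32))
        assert np.allclose(tx.roughness_sd(img, 5), brute_force_sd(img, 5),
                           atol=1e-10)

    def test_two_point_distribution_closed_form(self):
        # +/- a checkerboard: every odd window holds ceil/floor counts,
        # but a 3x3 window centered anywhere sees 5:4 or 4:5 — use a
        # column-stripe pattern with w covering equal counts instead
        a = 1.5
        img = np.where(np.arange(32)[None, :] % 2 == 0, a, -a) * np.ones((32, 1))
        out = tx.roughness_sd(img, 5)
        # 5-wide window over alternating columns sees 3:2 or 2:3 of ±a:
        # population SD = a*sqrt(24)/5
        expected = a * np.sqrt(24.0) / 5.0
        assert np.allclose(out[:, 2:-2], expected, atol=1e-10)

    def test_rotation_consistency(self, rng):
        img = rng.standard_normal((32, 32))
        assert np.allclose(tx.roughness_sd(np.rot90(img), 5),
                           np.rot90(tx.roughness_sd(img, 5)))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            tx.roughness_sd(np.zeros((10, 10)), 4)


class TestPrewittSlope:
    def test_constant_is_zero(self):
        assert np.allclose(tx.prewitt_slope(np.full((10, 10), 2.0)), 0.0)

    @pytest.mark.parametrize("s", [1.0, 0.25, 3.0])
    def test_ramp_normalization(self, s):
        img = s * np.arange(16)[None, :] * np.ones((16, 1))
        out = tx.prewitt_slope(img)
        assert np.allclose(out[1:-1, 1:-1], s)

    def test_diagonal_ramp_vector_sum(self):
        s = 0.5
        ii, jj = np.indices((16, 16))
        img = s * (ii + jj)
        out = tx.prewitt_slope(img)
        assert np.allclose(out[1:-1, 1:-1], s * np.sqrt(2.0))

    def test_rotation_consistency(self, rng):
        img = rng.standard_normal((24, 24))
        assert np.allclose(tx.prewitt_slope(np.rot90(img)),
                           np.rot90(tx.prewitt_slope(img)))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            tx.prewitt_slope(np.zeros((2, 5)))


class TestDepthCompensate:
    def test_noiseless_exponential_recovery(self):
        # mu = 1/mm, noiseless: fitted rate within 2% and compensated
        # profile flat within 2%
        cp = ph.default_class_params()
        cp[ph.TUMOR] = ph.ClassParams(1.0, 1e-9, 1.0, 24.0)
        spec = ph.PhantomSpec(layout_pattern="uniform_tumor", seed=1,
                              speckle_shape=0, noise_sd=0, surface_amp_vox=0,
                              surface_reflectivity=0, class_params=cp)
        p = ph.generate_phantom(spec)
        mask = np.ones_like(p.oct, dtype=bool)
        gain, comp = tx.depth_compensate(p.oct, mask)
        assert gain.rate_per_mm == pytest.approx(2.0, rel=0.02)
        profile = comp.mean(axis=(1, 2))
        assert profile.max() / profile.min() < 1.02

    def test_zero_rate_leaves_volume_unchanged(self):
        vol = np.full((30, 8, 8), 0.5)
        gain, comp = tx.depth_compensate(vol, np.ones_like(vol, bool))
        assert gain.rate_per_mm == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(comp, vol)

    def test_speckled_phantom_rate_recovery(self):
        spec = ph.PhantomSpec(layout_pattern="uniform_tumor", seed=3)
        p = ph.generate_phantom(spec)
        mask, _, _ = rp.segment_foreground(p.oct)
        gain, _ = tx.depth_compensate(p.oct, mask)
        mu = spec.class_params[ph.TUMOR].mu_per_mm
        assert gain.rate_per_mm == pytest.approx(2 * mu, rel=0.10)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            tx.depth_compensate(np.ones((10, 4, 4)), np.zeros((10, 4, 4), bool))

    def test_gain_normalized_at_surface(self):
        vol = np.exp(-0.5 * np.arange(40))[:, None, None] * np.ones((40, 6, 6))
        gain, _ = tx.depth_compensate(vol, np.ones_like(vol, bool))
        assert gain.gain[0] == pytest.approx(1.0)
        assert np.all(np.diff(gain.gain) > 0)


class TestRoiFeatures:
    def test_constant_roi(self):
        stack = tx.compute_feature_stack(np.full((40, 40), 2.5))
        f = tx.roi_features(stack, (4, 4, 20, 20))
        assert f.mean_intensity == pytest.approx(2.5)
        assert f.intensity_sd == 0.0
        assert f.mean_roughness_sd == 0.0
        assert f.mean_slope == 0.0
        assert f.intensity_entropy == 0.0
        assert f.local_contrast == pytest.approx(0.0, abs=1e-12)

    def test_uniform_16_level_entropy(self, rng):
        img = rng.integers(0, 16, size=(64, 64)).astype(float)
        stack = tx.compute_feature_stack(img)
        f = tx.roi_features(stack, (0, 0, 64, 64))
        assert f.intensity_entropy == pytest.approx(4.0, abs=0.05)

    def test_tumor_rougher_than_adipose_lumen_free_benign(self, default_phantoms):
        from octmargin import classify as cl
        zt = 8
        stacks = {}
        for name, pat in [("tumor", "uniform_tumor"), ("benign", "deep_focus")]:
            img = cl.log_scale(default_phantoms[pat].oct[zt])
            stacks[name] = tx.compute_feature_stack(img)
        ft = tx.roi_features(stacks["tumor"], (10, 10, 32, 32))
        fb = tx.roi_features(stacks["benign"], (10, 10, 32, 32))
        assert ft.mean_roughness_sd > fb.mean_roughness_sd

    def test_out_of_bounds_rejected(self):
        stack = tx.compute_feature_stack(np.zeros((30, 30)))
        with pytest.raises(ValueError):
            tx.roi_features(stack, (20, 20, 15, 15))
        with pytest.raises(ValueError):
            tx.roi_features(stack, (0, 0, 4, 4))
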