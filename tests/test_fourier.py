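"""Band-pass mask, patch filtering, pixel/area scores, and line profiles.

The FFT pipeline is cross-checked against brute-force DFT oracles built from
the transform definition (tests/oracle.py).
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ucnpscore as u
from ucnpscore.errors import EmptyMaskError, ShapeMismatchError, UCNPScoreError

from conftest import ring_patch
from oracle import brute_force_bandpass, brute_force_pixel_score, enumerate_band_bins

ALLPASS = u.BandpassSpec(r_inner=0.0, r_outer=1e6)


class TestBandpassMask:
    def test_allpass_spec_gives_all_ones(self):
        m = u.build_bandpass_mask(33, 1.0, ALLPASS)
        assert m.mask.shape == (33, 33)
        assert np.all(m.mask == 1)

    def test_default_band_excludes_dc(self):
        m = u.build_bandpass_mask(201, 0.25)
        assert m.mask[0, 0] == 0  # |f| = 0 < r_inner

    def test_mask_matches_exhaustive_enumeration(self):
        spec = u.BandpassSpec(0.1, 0.3)
        m = u.build_bandpass_mask(32, 1.0, spec)
        expected = enumerate_band_bins(32, 1.0, 0.1, 0.3)
        got = {(ky, kx) for ky, kx in zip(*np.nonzero(m.mask))}
        assert got == expected

    @pytest.mark.parametrize("n", [32, 33])
    def test_mask_symmetric_under_frequency_negation(self, n):
        m = u.build_bandpass_mask(n, 0.7, u.BandpassSpec(0.05, 0.5)).mask
        negated = np.roll(np.flip(m), shift=(1, 1), axis=(0, 1))
        np.testing.assert_array_equal(m, negated)

    def test_unreachable_band_raises_naming_range(self):
        with pytest.raises(EmptyMaskError, match="µm"):
            u.build_bandpass_mask(16, 1.0, u.BandpassSpec(0.001, 0.002))

    def test_invalid_radii_rejected(self):
        with pytest.raises(UCNPScoreError):
            u.BandpassSpec(0.5, 0.5)
        with pytest.raises(UCNPScoreError):
            u.BandpassSpec(-0.1, 0.5)


class TestBandpassPatch:
    def test_allpass_is_identity(self, rng):
        patch = rng.uniform(0, 100, (33, 33))
        mask = u.build_bandpass_mask(33, 1.0, ALLPASS)
        out = u.bandpass_patch(patch, mask)
        assert np.max(np.abs(out - patch)) <= 1e-10 * np.abs(patch).max()

    def test_constant_patch_annihilated_when_dc_excluded(self):
        mask = u.build_bandpass_mask(21, 1.0, u.BandpassSpec(0.01, 0.4))
        out = u.bandpass_patch(np.full((21, 21), 7.3), mask)
        assert np.max(np.abs(out)) < 1e-10

    def test_impulse_matches_brute_force_dft(self):
        patch = np.zeros((32, 32))
        patch[13, 20] = 1.0
        mask = u.build_bandpass_mask(32, 1.0, u.BandpassSpec(0.1, 0.3))
        got = u.bandpass_patch(patch, mask)
        want = brute_force_bandpass(patch, 1.0, 0.1, 0.3)
        assert np.max(np.abs(got - want)) <= 1e-6 * np.linalg.norm(patch)

    def test_shape_mismatch_rejected(self):
        mask = u.build_bandpass_mask(16, 1.0, ALLPASS)
        with pytest.raises(ShapeMismatchError):
            u.bandpass_patch(np.zeros((8, 8)), mask)


class TestGaussianWeight:
    def test_center_is_exactly_one(self):
        w = u.gaussian_weight(201, 34.0)
        assert w[100, 100] == 1.0

    def test_offset_sigma_matches_closed_form(self):
        w = u.gaussian_weight(201, 34.0)
        assert w[100 + 34, 100] == pytest.approx(np.exp(-0.5), abs=1e-12)

    def test_point_symmetry(self):
        w = u.gaussian_weight(65, 12.0)
        np.testing.assert_allclose(w, np.flip(w), atol=0)

    def test_even_window_centered_between_pixels(self):
        w = u.gaussian_weight(32, 8.0)
        np.testing.assert_allclose(w, np.flip(w), atol=0)
        assert w.max() < 1.0  # geometric center falls between pixels


class TestPixelScore:
    def test_zero_patch_scores_zero(self):
        mask = u.build_bandpass_mask(21, 1.0, u.BandpassSpec(0.01, 0.4))
        w = u.gaussian_weight(21, 5.0)
        assert u.pixel_score(np.zeros((21, 21)), mask, w) == 0.0

    def test_constant_patch_scores_zero_under_default_band(self):
        mask = u.build_bandpass_mask(33, 0.5)
        w = u.gaussian_weight(33, 34.0)
        assert u.pixel_score(np.full((33, 33), 42.0), mask, w) == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("mode", ["abs", "signed"])
    def test_ring_patch_matches_brute_force_oracle(self, mode):
        patch = ring_patch(64, radius=10, thickness=2, amplitude=100)
        mask = u.build_bandpass_mask(64, 1.0, u.BandpassSpec(0.01, 0.45))
        w = u.gaussian_weight(64, 34.0)
        got = u.pixel_score(patch, mask, w, magnitude_mode=mode)
        want = brute_force_pixel_score(patch, 1.0, 0.01, 0.45, 34.0, mode)
        assert got == pytest.approx(want, rel=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(c=st.floats(1e-3, 1e3), mode=st.sampled_from(["abs", "signed"]))
    def test_positive_homogeneity(self, c, mode):
        rng = np.random.default_rng(7)
        patch = rng.uniform(0, 50, (21, 21))
        mask = u.build_bandpass_mask(21, 1.0, u.BandpassSpec(0.05, 0.4))
        w = u.gaussian_weight(21, 8.0)
        s1 = u.pixel_score(patch, mask, w, mode)
        sc = u.pixel_score(c * patch, mask, w, mode)
        assert sc == pytest.approx(c * s1, rel=1e-9, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(offset=st.floats(-100, 100))
    def test_dc_offset_leaves_score_unchanged(self, offset):
        rng = np.random.default_rng(3)
        patch = rng.uniform(0, 50, (33, 33))
        mask = u.build_bandpass_mask(33, 0.5)  # default band, DC excluded
        w = u.gaussian_weight(33, 12.0)
        base = u.pixel_score(patch, mask, w)
        shifted = u.pixel_score(patch + offset, mask, w)
        assert shifted == pytest.approx(base, rel=1e-8, abs=1e-8)

    def test_off_center_ring_scores_strictly_less(self):
        """The Gaussian weight makes an isolated ring's score decay with
        its distance from the window center."""
        n = 201
        mask = u.build_bandpass_mask(n, 0.5)
        w = u.gaussian_weight(n, 34.0)
        scores = []
        for off in (0, 20, 60):
            patch = np.zeros((n, n))
            c = n // 2
            d = np.arange(n)
            dist = np.hypot(d[:, None] - c, d[None, :] - (c + off))
            patch[np.abs(dist - 12) <= 1.5] = 100.0
            scores.append(u.pixel_score(patch, mask, w))
        assert scores[0] > scores[1] > scores[2]


class TestScoreImage:
    def test_uniform_image_scores_zero(self):
        img = u.CalibratedImage(np.full((80, 80), 25.0), 0.5)
        psi = u.score_image(img, u.ScoringConfig(window_size=33, gaussian_sigma=10))
        np.testing.assert_allclose(psi.scores, 0.0, atol=1e-7)

    def test_valid_mode_geometry(self):
        img = u.CalibratedImage(np.zeros((250, 260)), 0.5)
        psi = u.score_image(img, u.ScoringConfig(window_size=201, gaussian_sigma=34))
        assert psi.scores.shape == (50, 60)
        assert psi.origin_offset == (100, 100)

    def test_image_smaller_than_window_rejected_in_valid_mode(self):
        img = u.CalibratedImage(np.zeros((50, 50)), 0.5)
        with pytest.raises(UCNPScoreError, match="smaller"):
            u.score_image(img, u.ScoringConfig(window_size=65, gaussian_sigma=10))

    def test_reflect_mode_scores_every_pixel(self):
        img = u.CalibratedImage(np.random.default_rng(0).uniform(0, 10, (40, 44)), 0.5)
        cfg = u.ScoringConfig(window_size=33, gaussian_sigma=10, edge_mode="reflect")
        psi = u.score_image(img, cfg)
        assert psi.scores.shape == (40, 44)
        assert psi.origin_offset == (0, 0)

    def test_stride_is_pure_decimation(self, small_spec):
        out = u.generate_phantom(small_spec)
        img = u.CalibratedImage(out.ucnp.pixels[:128, :128], small_spec.pixel_size)
        cfg1 = u.ScoringConfig(window_size=33, gaussian_sigma=10, stride=1)
        cfg4 = dataclasses.replace(cfg1, stride=4)
        full = u.score_image(img, cfg1)
        dec = u.score_image(img, cfg4)
        np.testing.assert_array_equal(dec.scores, full.scores[::4, ::4])

    def test_rfft_batch_path_equals_per_patch_full_fft(self, rng):
        """The half-spectrum batch path must agree with the complex-FFT
        single-patch path to round-off."""
        pixels = rng.uniform(0, 200, (60, 60))
        img = u.CalibratedImage(pixels, 0.5)
        cfg = u.ScoringConfig(window_size=33, gaussian_sigma=10, stride=7)
        psi = u.score_image(img, cfg)
        mask = u.build_bandpass_mask(33, 0.5, cfg.band)
        w = u.gaussian_weight(33, 10)
        for i in range(psi.scores.shape[0]):
            for j in range(psi.scores.shape[1]):
                patch = pixels[i * 7 : i * 7 + 33, j * 7 : j * 7 + 33]
                assert psi.scores[i, j] == pytest.approx(
                    u.pixel_score(patch, mask, w), rel=1e-10, abs=1e-9
                )

    def test_even_window_rejected_in_config(self):
        with pytest.raises(UCNPScoreError, match="odd"):
            u.ScoringConfig(window_size=200)


class TestAreaScore:
    def test_constant_grid(self, small_config):
        psi = u.PixelScoreImage(np.full((4, 5), 3.0), (0, 0), 1, small_config, 0.5)
        a = u.area_score(psi)
        assert (a.mean, a.std, a.n_pixels) == (3.0, 0.0, 20)

    def test_two_point_arithmetic(self, small_config):
        psi = u.PixelScoreImage(np.array([[1.0, 3.0]]), (0, 0), 1, small_config, 0.5)
        a = u.area_score(psi)
        assert a.mean == 2.0 and a.std == 1.0  # population divisor

    def test_cpa_level_means_strictly_ordered(self, cpa_small):
        _, scores = cpa_small
        means = {lvl: np.mean([a.mean for a in s]) for lvl, s in scores.items()}
        assert (
            means[u.HER2Level.THREE_PLUS]
            > means[u.HER2Level.TWO_PLUS]
            > means[u.HER2Level.ONE_PLUS]
        )


class TestSaveLoadPixelScores:
    def test_round_trip_preserves_geometry_and_config(self, tmp_path, small_config):
        scores = np.arange(12.0).reshape(3, 4)
        psi = u.PixelScoreImage(scores, (32, 32), 8, small_config, 0.5)
        path = tmp_path / "scores.tif"
        u.save_pixel_scores(psi, path)
        back = u.load_pixel_scores(path)
        np.testing.assert_allclose(back.scores, scores, rtol=1e-6)
        assert back.origin_offset == (32, 32)
        assert back.stride == 8
        assert back.config.window_size == small_config.window_size
        assert back.config.band == small_config.band


class TestLineProfile:
    def test_constant_patch_single_dc_peak(self):
        prof = u.fft_line_profile(np.full((33, 33), 2.0), 1.0)
        freqs, mags = prof[:, 0], prof[:, 1]
        assert mags[np.argwhere(freqs == 0)[0, 0]] > 0
        assert np.all(mags[freqs != 0] < 1e-9)

    def test_grid_aligned_cosine_peaks_at_its_frequency(self):
        n, k0 = 65, 5
        x = np.arange(n)
        patch = np.tile(np.cos(2 * np.pi * k0 * x / n), (n, 1))
        prof = u.fft_line_profile(patch, pixel_size=2.0)
        freqs, mags = prof[:, 0], prof[:, 1]
        f0 = k0 / (n * 2.0)
        peak_bins = np.isclose(np.abs(freqs), f0)
        assert np.all(mags[peak_bins] > 1.0)
        assert np.all(mags[~peak_bins] < 1e-10 * mags.max())

    def test_ring_profile_matches_direct_dft_peak_location(self):
        patch = ring_patch(33, radius=8, thickness=2, amplitude=50)
        prof = u.fft_line_profile(patch, pixel_size=1.0, axis="horizontal")
        from oracle import dft_matrix

        W = dft_matrix(33)
        mag = np.abs(np.fft.fftshift(W @ patch @ W.T))
        want_line = mag[16, :]
        np.testing.assert_allclose(prof[:, 1], want_line, rtol=1e-9, atol=1e-9)

    def test_even_patch_rejected(self):
        with pytest.raises(UCNPScoreError, match="odd"):
            u.fft_line_profile(np.zeros((32, 32)), 1.0)
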