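import numpy as np
import pytest

import respicam as rc
from respicam.preprocess import sliding_windows
from respicam.rr import (
    PixelSelection,
    bandpass,
    normalize01,
    select_pixels,
    spectrum_peak_bpm,
    windowed_spectrum,
)

from conftest import naive_half_spectrum

T72 = np.arange(72) / 9.0


class TestSpectralContext:
    def test_grid_constants(self, ctx):
        assert ctx.n_samples == 72
        assert ctx.nz == 8640
        assert ctx.n_bins == 4320
        assert ctx.bin_hz == pytest.approx(9.0 / 8640.0)
        assert ctx.harmonic_tol_hz == pytest.approx(0.125)

    def test_band_below_nyquist(self, ctx):
        assert ctx.lim1 < ctx.lim2 < 4.5

    def test_rejects_bad_band(self):
        with pytest.raises(ValueError):
            rc.SpectralContext(lim1=2.0, lim2=1.0)


class TestPixelSpectra:
    def test_constant_pixel_differential_is_zero(self, ctx):
        spec = rc.pixel_spectra(np.full((72, 1), 3.0), ctx, differential=True)
        np.testing.assert_allclose(spec, 0.0, atol=1e-12)

    def test_dc_without_differential_peaks_at_k0(self, ctx):
        spec = rc.pixel_spectra(np.full((72, 1), 3.0), ctx, differential=False)
        assert spec[0].argmax() == 0
        assert spec[0, 0] > 0

    def test_sinusoid_argmax_within_one_bin(self, ctx):
        x = np.sin(2 * np.pi * 0.667 * T72)
        spec = rc.pixel_spectra(x[:, None], ctx, differential=True)
        f = ctx.freqs[spec[0].argmax()]
        assert abs(f - 0.667) <= ctx.bin_hz

    def test_matches_naive_dft_oracle(self, ctx):
        x = np.sin(2 * np.pi * 0.667 * T72) + 0.1 * np.cos(2 * np.pi * 1.3 * T72)
        spec = rc.pixel_spectra(x[:, None], ctx, differential=True)[0]
        oracle = naive_half_spectrum(np.diff(x), ctx.nz)
        np.testing.assert_allclose(spec, oracle, atol=1e-8)

    def test_too_few_samples_raises(self, ctx):
        with pytest.raises(ValueError):
            rc.pixel_spectra(np.zeros((3, 1)), ctx)


class TestPseudoPeriodicity:
    def test_single_nonzero_bin_gives_one(self):
        spec = np.zeros((1, 100))
        spec[0, 17] = 4.2
        assert rc.pseudo_periodicity(spec)[0] == pytest.approx(1.0)

    def test_two_equal_bins_give_inv_sqrt2(self):
        spec = np.zeros((1, 100))
        spec[0, [10, 20]] = 3.0
        assert rc.pseudo_periodicity(spec)[0] == pytest.approx(1.0 / np.sqrt(2.0))

    def test_zero_spectrum_gives_zero(self):
        assert rc.pseudo_periodicity(np.zeros((1, 50)))[0] == 0.0

    def test_bounded_by_one(self, ctx):
        rng = np.random.default_rng(2)
        spec = np.abs(rng.normal(size=(20, ctx.n_bins)))
        q = rc.pseudo_periodicity(spec)
        assert np.all((q >= 0) & (q <= 1))

    def test_sinusoid_beats_noise_over_seeded_draws(self, ctx):
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(100):
            noise = rng.normal(size=72)
            sine = np.sin(2 * np.pi * 0.7 * T72 + rng.uniform(0, 2 * np.pi))
            q = rc.pseudo_periodicity(
                rc.pixel_spectra(np.column_stack([noise, sine]), ctx, differential=True)
            )
            wins += q[1] > q[0]
        assert wins == 100


class TestDominantFrequency:
    def _spectra(self, x, ctx):
        yd = rc.pixel_spectra(x[:, None], ctx, differential=True)
        yp = rc.pixel_spectra(x[:, None], ctx, differential=False)
        return yd, yp

    def test_harmonic_disambiguation_returns_fundamental(self, ctx):
        # differentiation promotes the 1.2 Hz harmonic above 0.6 Hz in y'
        # while y keeps the fundamental dominant -> Eq conditions fire
        x = np.sin(2 * np.pi * 0.6 * T72) + 0.6 * np.sin(2 * np.pi * 1.2 * T72)
        yd, yp = self._spectra(x, ctx)
        # verify the premise on the two spectra
        k06 = int(round(0.6 / ctx.bin_hz))
        k12 = int(round(1.2 / ctx.bin_hz))
        assert yd[0, k12] > yd[0, k06]
        assert yp[0, k12] < yp[0, k06]
        rr = rc.dominant_frequency(yd, yp, ctx)[0]
        assert abs(rr - 0.6) <= ctx.bin_hz

    def test_supra_band_oscillation_suppressed(self, ctx):
        x = np.sin(2 * np.pi * 2.5 * T72)
        yd, yp = self._spectra(x, ctx)
        assert rc.dominant_frequency(yd, yp, ctx)[0] == 0.0

    def test_pure_in_band_tone(self, ctx):
        x = np.sin(2 * np.pi * 1.0 * T72)
        yd, yp = self._spectra(x, ctx)
        rr = rc.dominant_frequency(yd, yp, ctx)[0]
        assert abs(rr - 1.0) <= ctx.bin_hz

    def test_mismatched_shapes_raise(self, ctx):
        with pytest.raises(ValueError):
            rc.dominant_frequency(np.zeros((1, 10)), np.zeros((1, 11)), ctx)


class TestClusterFilter:
    def test_uniform_patch_center_is_one(self):
        w = rc.cluster_filter(np.full((3, 3), 0.7))
        assert w[1, 1] == pytest.approx(1.0)

    def test_suppressed_center_gives_zero(self):
        rr_hat = np.full((3, 3), 0.7)
        rr_hat[1, 1] = 0.0
        assert rc.cluster_filter(rr_hat)[1, 1] == 0.0

    def test_hand_computed_neighbourhood(self):
        # center 0.7, eight neighbours 0.8 -> (1 + 8 exp(-10)) / 9
        rr_hat = np.full((3, 3), 0.8)
        rr_hat[1, 1] = 0.7
        expected = (1.0 + 8.0 * np.exp(-70.0 * 0.1 / 0.7)) / 9.0
        assert rc.cluster_filter(rr_hat)[1, 1] == pytest.approx(expected)

    def test_borders_are_zero(self):
        w = rc.cluster_filter(np.full((5, 6), 0.7))
        assert np.all(w[0] == 0) and np.all(w[-1] == 0)
        assert np.all(w[:, 0] == 0) and np.all(w[:, -1] == 0)
        assert np.all(w[1:-1, 1:-1] == pytest.approx(1.0))

    def test_zero_neighbours_attenuate_but_stay_finite(self):
        rr_hat = np.zeros((3, 3))
        rr_hat[1, 1] = 0.7
        w = rc.cluster_filter(rr_hat)
        assert w[1, 1] == pytest.approx(1.0 / 9.0)


class TestGradientFeature:
    def test_constant_image_all_zero(self):
        assert not rc.gradient_feature(np.full((10, 6, 8), 7.0)).any()

    def test_step_edge_detected(self):
        # step of the full window range R: per-pixel gradient ~R > R/16
        samples = np.zeros((10, 8, 8))
        samples[:, :, 4:] = 10.0
        g = rc.gradient_feature(samples)
        assert g[:, 3:5].all()
        assert not g[:, :3].any() and not g[:, 6:].any()

    def test_smooth_ramp_below_threshold(self):
        # slope R/100 per pixel < R/16 -> no edges anywhere
        ramp = np.linspace(0.0, 8.0 * 10.0 / 100.0, 8)
        samples = np.tile(ramp, (10, 8, 1))
        samples[0, 0, 0] = 10.0  # pins the window range to ~10
        g = rc.gradient_feature(samples)
        assert g.sum() <= 2  # only the range-pinning pixel may fire


class TestFuseAndPickCore:
    def test_jointly_maximal_pixel_is_core(self):
        Q = np.ones((4, 4)) * 0.2
        W = np.ones((4, 4)) * 0.2
        G = np.zeros((4, 4))
        Q[2, 3], W[2, 3], G[2, 3] = 1.0, 1.0, 1.0
        V, core = rc.fuse_and_pick_core(Q, W, G)
        assert core == (2, 3)

    def test_zero_gradient_vetoes(self):
        Q = np.ones((3, 3))
        W = np.ones((3, 3))
        G = np.zeros((3, 3))
        G[0, 0] = 1
        V, core = rc.fuse_and_pick_core(Q, W, G)
        assert V[1, 1] == 0.0

    def test_all_zero_v_flags_no_core(self):
        zeros = np.zeros((3, 3))
        V, core = rc.fuse_and_pick_core(zeros, zeros, zeros)
        assert core is None

    def test_motion_pixel_with_zero_w_rejected(self):
        # high Q, g = 1 but w = 0 -> V = 0 there (type-2 region veto)
        Q = np.full((3, 3), 0.5)
        W = np.full((3, 3), 0.5)
        G = np.ones((3, 3), np.uint8)
        Q[0, 1] = 1.0
        W[0, 1] = 0.0
        V, core = rc.fuse_and_pick_core(Q, W, G)
        assert V[0, 1] == 0.0
        assert core != (0, 1)

    def test_constant_map_normalizes_to_zero(self):
        assert not normalize01(np.full((3, 3), 5.0)).any()


class TestSelectPixels:
    def _window(self, ctx, rng, n_px=6, snr_bad=0.1):
        sine = np.sin(2 * np.pi * 0.7 * T72)
        cols = [sine + 0.01 * rng.normal(size=72) for _ in range(n_px - 2)]
        cols.append(-sine + 0.01 * rng.normal(size=72))  # inverted copy
        cols.append(snr_bad * sine + rng.normal(size=72))  # buried in noise
        return np.stack(cols, axis=1).reshape(72, 1, n_px)

    def test_core_is_always_member(self, ctx):
        samples = self._window(ctx, np.random.default_rng(0))
        sel = rc.select_pixels(samples, (0, 0), ctx)
        assert [0, 0] in sel.members.tolist()

    def test_negative_copy_is_member(self, ctx):
        # |c| > kappa3, sign ignored
        samples = self._window(ctx, np.random.default_rng(1))
        sel = rc.select_pixels(samples, (0, 0), ctx)
        assert [0, samples.shape[2] - 2] in sel.members.tolist()

    def test_noise_buried_pixel_excluded(self, ctx):
        rng = np.random.default_rng(2)
        for _ in range(10):
            samples = self._window(ctx, rng)
            sel = rc.select_pixels(samples, (0, 0), ctx)
            assert [0, samples.shape[2] - 1] not in sel.members.tolist()

    def test_zero_variance_pixel_excluded(self, ctx):
        samples = self._window(ctx, np.random.default_rng(3))
        samples[:, 0, 1] = 5.0
        sel = rc.select_pixels(samples, (0, 0), ctx)
        assert [0, 1] not in sel.members.tolist()


class TestEstimateRR:
    def test_40bpm_cluster_recovered(self, ctx):
        rng = np.random.default_rng(4)
        sine = np.sin(2 * np.pi * (40.0 / 60.0) * T72)
        samples = (sine[:, None] + 0.02 * rng.normal(size=(72, 5))).reshape(72, 1, 5)
        sel = rc.select_pixels(samples, (0, 2), ctx)
        bpm, spec = rc.estimate_rr(sel, ctx)
        assert abs(bpm - 40.0) <= 3.75

    def test_duplicate_members_idempotent(self, ctx):
        series = bandpass(np.sin(2 * np.pi * 0.8 * T72), ctx)
        one = PixelSelection((0, 0), np.array([[0, 0]]), np.array([1.0]), series[:, None])
        two = PixelSelection(
            (0, 0), np.array([[0, 0], [0, 1]]), np.ones(2), np.column_stack([series, series])
        )
        assert rc.estimate_rr(one, ctx)[0] == rc.estimate_rr(two, ctx)[0]

    def test_peak_matches_naive_dft_oracle(self, ctx):
        rng = np.random.default_rng(6)
        raw = np.sin(2 * np.pi * 0.9 * T72) + 0.05 * rng.normal(size=72)
        filt = bandpass(raw, ctx)
        sel = PixelSelection((0, 0), np.array([[0, 0]]), np.array([1.0]), filt[:, None])
        bpm, spec = rc.estimate_rr(sel, ctx)
        oracle = naive_half_spectrum(filt, ctx.nz)
        assert bpm == pytest.approx(60.0 * ctx.freqs[oracle.argmax()])

    def test_empty_selection_gives_none(self, ctx):
        sel = PixelSelection((0, 0), np.empty((0, 2)), np.empty(0), np.empty((72, 0)))
        bpm, spec = rc.estimate_rr(sel, ctx)
        assert bpm is None and spec is None


class TestReferenceRR:
    def test_50bpm_waveform(self, ctx):
        t = np.arange(int(20 * 62.5)) / 62.5
        rows = rc.reference_rr(t, np.sin(2 * np.pi * (50.0 / 60.0) * t), ctx)
        assert len(rows) == 13
        for row in rows:
            assert abs(row["bpm"] - 50.0) <= 1.0

    def test_one_pixel_video_path_identical(self, ctx):
        # the video estimator on a single pixel and the reference path share
        # the spectral code, so the rates agree exactly on uniform input
        rng = np.random.default_rng(8)
        t = np.arange(72) / 9.0
        series = np.sin(2 * np.pi * 0.75 * t) + 0.05 * rng.normal(size=72)
        ref_rows = rc.reference_rr(t, series, ctx)
        filt = bandpass(series, ctx)
        sel = PixelSelection((0, 0), np.array([[0, 0]]), np.array([1.0]), filt[:, None])
        bpm, _ = rc.estimate_rr(sel, ctx)
        assert ref_rows[0]["bpm"] == pytest.approx(bpm)

    def test_constant_waveform_flagged(self, ctx):
        t = np.arange(int(10 * 62.5)) / 62.5
        rows = rc.reference_rr(t, np.ones_like(t), ctx)
        assert all(row["bpm"] is None for row in rows)


class TestBuildStft:
    def test_single_window(self, ctx):
        spec = np.arange(ctx.n_bins, dtype=float)
        stft = rc.build_stft([spec], ctx)
        assert stft.shape == (1, ctx.n_bins)
        np.testing.assert_array_equal(stft[0], spec)

    def test_missing_windows_are_nan_rows(self, ctx):
        spec = np.ones(ctx.n_bins)
        stft = rc.build_stft([spec, None, spec], ctx)
        assert np.isnan(stft[1]).all()
        assert not np.isnan(stft[[0, 2]]).any()

    def test_stationary_input_rows_nearly_identical(self, ctx, still_recording):
        wins = sliding_windows(still_recording.stacks[0])
        specs = [rc.analyze_window(w.samples, ctx).spectrum for w in wins[:4]]
        stft = rc.build_stft(specs, ctx)
        peak_bins = np.nanargmax(stft, axis=1)
        assert np.ptp(peak_bins) <= 8  # stationary rate: peaks in one small band


class TestAffineInvariance:
    def test_features_invariant_to_gain(self, ctx, still_recording):
        win = sliding_windows(still_recording.stacks[0])[0]
        a = rc.analyze_window(win.samples, ctx)
        b = rc.analyze_window(3.0 * win.samples, ctx)
        np.testing.assert_allclose(a.features.Q, b.features.Q, atol=1e-9)
        np.testing.assert_allclose(a.features.W, b.features.W, atol=1e-9)
        np.testing.assert_array_equal(a.features.G, b.features.G)
        np.testing.assert_allclose(a.features.V, b.features.V, atol=1e-9)
        assert a.rr_bpm == pytest.approx(b.rr_bpm, abs=1e-9)

    def test_offset_free_paths_invariant_to_offset(self, ctx, still_recording):
        # an intensity offset cancels exactly in the differenced spectra (Q),
        # in the window range (G) and in the band-passed rate estimate; the
        # undifferenced spectrum used by the harmonic check picks up DC
        # leakage, so W may differ at isolated noise pixels
        win = sliding_windows(still_recording.stacks[0])[0]
        a = rc.analyze_window(win.samples, ctx)
        b = rc.analyze_window(win.samples + 100.0, ctx)
        np.testing.assert_allclose(a.features.Q, b.features.Q, atol=1e-9)
        np.testing.assert_array_equal(a.features.G, b.features.G)
        assert a.rr_bpm == pytest.approx(b.rr_bpm, abs=1e-6)


class TestEndToEndRecovery:
    @pytest.mark.parametrize("bpm", [30.0, 40.0, 50.0, 60.0, 80.0])
    def test_in_band_rate_recovered(self, ctx, bpm):
        spec = rc.SceneSpec(
            shape=(16, 24),
            duration_s=12.0,
            noise_sigma=0.05,
            cluster=rc.ClusterSpec(region=(5, 11, 8, 16), rr_bpm=bpm, amplitude=1.0, edge_step=4.0),
            seed=int(bpm),
        )
        rec = rc.generate(spec)
        for w in sliding_windows(rec.stacks[0]):
            res = rc.analyze_window(w.samples, ctx)
            assert res.rr_bpm is not None
            assert abs(res.rr_bpm - bpm) <= 3.75
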