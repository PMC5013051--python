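"""Signal-conditioning contracts: interpolation, interference removal,
label refinement, envelopes, resampling, smoothing, normalization."""

import numpy as np
import pytest
from scipy import signal as sps

from semgkit import preprocessing as pp
from semgkit.types import Recording, WindowSet


class TestSynchronizeStreams:
    def test_stream_at_target_rate_returned_unchanged(self):
        x = np.arange(10.0)
        (out,) = pp.synchronize_streams([(x, 5.0)], 5.0)
        assert out is x

    def test_ramp_supersampling_is_linear_interpolation(self):
        (out,) = pp.synchronize_streams([(np.array([0.0, 1.0, 2.0]), 1.0)], 2.0)
        assert np.allclose(out, [0.0, 0.5, 1.0, 1.5, 2.0])

    def test_mixed_rate_streams_get_equal_lengths(self):
        slow = np.ones(101)  # 1 s at 100 Hz
        fast = np.ones((2001, 3))  # 1 s at 2 kHz
        out = pp.synchronize_streams([(slow, 100.0), (fast, 2000.0)], 2000.0)
        assert out[0].shape[0] == out[1].shape[0] == 2001

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            pp.synchronize_streams([(np.array([1.0]), 10.0)], 20.0)


@pytest.fixture(scope="module")
def noisy():
    rng = np.random.default_rng(5)
    fs, n = 2000.0, 40000
    sos = sps.butter(4, [20, 450], btype="bandpass", fs=fs, output="sos")
    clean = sps.sosfiltfilt(sos, rng.standard_normal(n))
    t = np.arange(n) / fs
    return fs, clean, clean + np.sin(2 * np.pi * 50.0 * t)


class TestHampel:
    def test_tone_attenuated_without_touching_out_of_band(self, noisy):
        fs, _, x = noisy
        y = pp.hampel_powerline_filter(x, fs)
        f, px = sps.periodogram(x, fs)
        _, py = sps.periodogram(y, fs)
        i50 = np.argmin(np.abs(f - 50.0))
        att_db = 10 * np.log10(px[i50 - 1 : i50 + 2].sum() / py[i50 - 1 : i50 + 2].sum())
        oob = np.abs(f - 50.0) > 2.0
        oob_change = abs(py[oob].sum() - px[oob].sum()) / px[oob].sum()
        assert att_db >= 20.0
        assert oob_change < 0.05
        assert y.size == x.size

    def test_interference_free_signal_nearly_unchanged(self, noisy):
        fs, clean, _ = noisy
        y = pp.hampel_powerline_filter(clean, fs)
        rel = np.sqrt(np.mean((y - clean) ** 2)) / clean.std()
        assert rel < 0.01

    def test_dc_signal_unchanged(self):
        x = np.full(1000, 3.0)
        assert np.allclose(pp.hampel_powerline_filter(x, 2000.0), x)

    def test_base_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.hampel_powerline_filter(np.zeros(100), 80.0, base=50.0)


class TestRelabelGLR:
    def test_known_lag_recovered_within_50ms(self, small_raw_recording):
        proto, _, rec, truth = small_raw_recording
        refined = pp.relabel_glr(rec)
        stim = refined.stimulus
        starts = np.flatnonzero(np.diff((stim > 0).astype(int)) == 1) + 1
        errors = np.abs(starts - truth.true_onsets) / proto.sampling_rate
        assert np.median(errors) < 0.05
        # class ids and segment count preserved
        assert np.array_equal(np.unique(stim), np.unique(rec.stimulus))
        assert starts.size == truth.true_onsets.size

    def test_lag_free_recording_is_boundary_stable(self):
        from semgkit import synthetic

        proto = synthetic.ProtocolSpec(
            n_movement_classes=3, n_repetitions=2, movement_duration=2.0,
            rest_duration=2.0, sampling_rate=2000.0, n_channels=3,
        )
        sig = synthetic.make_class_signatures(3, 3, 5.0, seed=2)
        noise = synthetic.NoiseSettings(lag_range=(0.0, 0.0))
        rec, truth = synthetic.generate_recording(proto, sig, noise, seed=3)
        refined = pp.relabel_glr(rec, search_margin=0.8)
        stim = refined.stimulus
        starts = np.flatnonzero(np.diff((stim > 0).astype(int)) == 1) + 1
        assert np.median(np.abs(starts - truth.nominal_onsets)) / 2000.0 <= 0.05

    def test_constant_variance_signal_keeps_nominal_boundaries(self):
        rng = np.random.default_rng(7)
        n, fs = 40000, 2000.0
        stim = np.zeros(n, dtype=int)
        rep = np.zeros(n, dtype=int)
        stim[8000:16000] = 1
        rep[8000:16000] = 1
        rec = Recording(
            emg=rng.standard_normal((n, 4)), stimulus=stim, repetition=rep, sampling_rate=fs
        )
        refined = pp.relabel_glr(rec, search_margin=1.0)
        assert np.array_equal(refined.stimulus, stim)


class TestEnvelopesAndResampling:
    def test_rms_rectify_constant_and_zero(self):
        c = -3.0 * np.ones((500, 2))
        out = pp.rms_rectify(c, 100.0, 0.1)
        assert np.allclose(out, 3.0)
        assert np.allclose(pp.rms_rectify(np.zeros((100, 1)), 100.0, 0.1), 0.0)

    def test_rms_rectify_sine_matches_closed_form(self):
        fs = 1000.0
        t = np.arange(int(fs * 2)) / fs
        x = np.sin(2 * np.pi * 10 * t)[:, None]  # window of 0.1 s = 1 period
        out = pp.rms_rectify(x, fs, 0.1)
        interior = out[200:-200, 0]
        assert np.allclose(interior, 1 / np.sqrt(2), atol=0.01)

    def test_rms_rectify_subsample_window_rejected(self):
        with pytest.raises(ValueError):
            pp.rms_rectify(np.zeros((100, 1)), 100.0, 0.01)

    def test_resample_identity_and_length(self):
        x = np.ones((20000, 2))
        assert pp.resample_to(x, 2000.0, 2000.0).shape == x.shape
        out = pp.resample_to(x, 2000.0, 200.0)
        assert abs(out.shape[0] - 2000) <= 1

    def test_resample_preserves_dominant_frequency(self):
        fs = 2000.0
        t = np.arange(int(fs * 10)) / fs
        x = np.sin(2 * np.pi * 5.0 * t)
        y = pp.resample_to(x, fs, 200.0)
        f, p = sps.periodogram(y, 200.0)
        assert abs(f[np.argmax(p)] - 5.0) < 0.2

    def test_lowpass_dc_unchanged_and_tones_separated(self):
        fs = 200.0
        dc = np.full(2000, 2.5)
        assert np.allclose(pp.lowpass_envelope(dc, 1.0, fs), 2.5)
        t = np.arange(int(fs * 30)) / fs
        x = np.sin(2 * np.pi * 0.2 * t) + np.sin(2 * np.pi * 20.0 * t)
        y = pp.lowpass_envelope(x, 1.0, fs)

        def amp(sig, freq):
            c = np.cos(2 * np.pi * freq * t)
            s = np.sin(2 * np.pi * freq * t)
            return 2 * np.hypot(sig @ c / t.size, sig @ s / t.size)

        assert amp(y, 0.2) == pytest.approx(1.0, rel=0.05)
        assert 20 * np.log10(amp(x, 20.0) / max(amp(y, 20.0), 1e-12)) >= 30.0

    def test_lowpass_reduces_white_noise_variance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(5000)
        assert pp.lowpass_envelope(x, 1.0, 200.0).var() < x.var()

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            pp.lowpass_envelope(np.zeros(100), 150.0, 200.0)


class TestNormalization:
    @pytest.fixture()
    def windows(self):
        rng = np.random.default_rng(3)
        return WindowSet(
            samples=2.0 + 3.0 * rng.standard_normal((40, 30, 4)),
            labels=np.zeros(40, dtype=int),
            repetitions=np.ones(40, dtype=int),
            t_start=np.arange(40.0),
            sampling_rate=200.0,
        )

    def test_none_is_identity(self, windows):
        assert pp.normalize_windows(windows, "none") is windows

    def test_per_window_standardizes_each_window(self, windows):
        out = pp.normalize_windows(windows, "per_window")
        means = out.samples.mean(axis=(1, 2))
        stds = out.samples.std(axis=(1, 2))
        assert np.allclose(means, 0.0, atol=1e-6)
        assert np.allclose(stds, 1.0, atol=1e-6)

    def test_train_stats_standardizes_training_pool(self, windows):
        stats = pp.compute_window_stats(windows)
        out = pp.normalize_windows(windows, "train_stats", stats)
        flat = out.samples.reshape(-1, out.n_channels)
        assert np.allclose(flat.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(flat.std(axis=0), 1.0, atol=1e-6)

    def test_constant_window_epsilon_guarded(self):
        ws = WindowSet(
            samples=np.full((2, 10, 2), 7.0),
            labels=np.zeros(2, dtype=int),
            repetitions=np.ones(2, dtype=int),
            t_start=np.zeros(2),
            sampling_rate=100.0,
        )
        out = pp.normalize_windows(ws, "per_window")
        assert np.isfinite(out.samples).all()


class TestBranchPipelines:
    def test_cnn_branch_order_and_rates(self, small_raw_recording):
        _, _, rec, _ = small_raw_recording
        out, log = pp.preprocess_for_cnn(rec)
        stages = [line.split(":")[0] for line in log]
        assert stages == ["hampel", "relabel_glr", "rms_rectify", "resample", "lowpass"]
        assert out.sampling_rate == 200.0
        assert out.n_channels == rec.n_channels
        assert np.all(out.emg.min(axis=0) > -0.5)  # envelope, near-nonnegative

    def test_rectified_branch_skips_interference_and_rectification(self, small_rect_recording):
        _, _, rec, _ = small_rect_recording
        out, log = pp.preprocess_for_cnn(rec, pp.PreprocessConfig(relabel_margin=0.3))
        stages = [line.split(":")[0] for line in log]
        assert stages == ["relabel_glr", "lowpass"]
        assert out.sampling_rate == 100.0

    def test_classical_branch_keeps_native_rate(self, small_raw_recording):
        _, _, rec, _ = small_raw_recording
        out, log = pp.preprocess_for_classical(rec)
        stages = [line.split(":")[0] for line in log]
        assert stages == ["hampel", "relabel_glr"]
        assert out.sampling_rate == rec.sampling_rate
        assert out.n_samples == rec.n_samples
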