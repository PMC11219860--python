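import numpy as np
import pytest
from scipy import optimize, signal

from allolight import photometry as phot
from allolight.errors import NonPositiveBaselineError
from allolight.photometry import (
    DffTrace,
    PhotometryRecording,
    TrialTable,
    align_trials,
    compute_dff,
    detect_spontaneous_peaks,
    longform_bleach_correct,
    normalize_to_vehicle,
    off_decay_time,
    preprocess,
    stable_window,
    tonic_baseline,
    transient_metrics,
)


def make_recording(ref, sig, fs=100.0):
    n = len(ref)
    return PhotometryRecording(time=np.arange(n) / fs, reference=np.asarray(ref, float),
                               signal=np.asarray(sig, float), fs=fs)


def make_dff(values, fs=10.0):
    v = np.asarray(values, float)
    return DffTrace(time=np.arange(v.size) / fs, dff=v, fs=fs)


class TestPreprocess:
    def test_factor_one_without_filter_is_identity(self, rng):
        rec = make_recording(rng.normal(100, 1, 256), rng.normal(80, 1, 256))
        out = preprocess(rec, downsample_factor=1, lowpass_hz=None)
        np.testing.assert_array_equal(out.signal, rec.signal)
        assert out.fs == rec.fs

    def test_acquisition_rate_after_tenfold_downsampling(self, rng):
        rec = make_recording(rng.normal(100, 1, 20346), rng.normal(80, 1, 20346),
                             fs=1017.3)
        out = preprocess(rec, downsample_factor=10, lowpass_hz=2.0)
        assert out.fs == pytest.approx(101.73)
        assert out.n_samples == 2034

    def test_lowpass_attenuates_high_frequencies(self, rng):
        rec = make_recording(rng.standard_normal(8192), rng.standard_normal(8192))
        out = preprocess(rec, downsample_factor=1, lowpass_hz=1.0)
        f, pxx_in = signal.periodogram(rec.signal, rec.fs)
        _, pxx_out = signal.periodogram(out.signal, out.fs)
        band = f > 2.0
        atten_db = 10 * np.log10(pxx_in[band].mean() / pxx_out[band].mean())
        assert atten_db >= 20.0

    def test_cutoff_above_new_nyquist_rejected(self, rng):
        rec = make_recording(rng.normal(size=1000), rng.normal(size=1000), fs=100.0)
        with pytest.raises(ValueError):
            preprocess(rec, downsample_factor=50, lowpass_hz=2.0)


class TestComputeDff:
    def test_identical_channels_give_zero(self, rng):
        x = rng.uniform(50, 150, 500)
        assert np.allclose(compute_dff(make_recording(x, x)).dff, 0.0)

    def test_affine_relation_gives_zero(self, rng):
        ref = rng.uniform(50, 150, 500)
        assert np.allclose(compute_dff(make_recording(ref, 2 * ref + 5)).dff, 0.0,
                           atol=1e-9)

    def test_transient_survives_motion_removal(self, rng):
        n, fs = 2000, 100.0
        motion = 1 + 0.05 * np.sin(2 * np.pi * 0.5 * np.arange(n) / fs)
        ref = 80 * motion
        transient = np.zeros(n)
        transient[1000:1100] = 10.0  # 10% square transient
        sig = 100 * motion * (1 + transient / 100)
        # fit the reference on transient-free samples, as for event-related data
        dff = compute_dff(make_recording(ref, sig, fs), fit_scope=[(0.0, 9.0)])
        assert np.median(dff.dff[1000:1100]) == pytest.approx(10.0, abs=0.5)
        assert np.abs(dff.dff[:900]).max() < 0.5

    def test_gain_invariance(self, rng):
        ref = rng.uniform(50, 150, 400)
        sig = 1.5 * ref + rng.normal(0, 1, 400) + 10
        rec = make_recording(ref, sig)
        scaled = make_recording(3.0 * ref, 3.0 * sig)
        np.testing.assert_allclose(compute_dff(rec).dff, compute_dff(scaled).dff,
                                   atol=1e-9)

    def test_scope_window_restricts_fit(self, rng):
        ref = rng.uniform(90, 110, 1000)
        sig = 2.0 * ref
        sig[500:] += 50.0  # tonic change outside the fit scope
        rec = make_recording(ref, sig, fs=100.0)
        dff = compute_dff(rec, fit_scope=[(0.0, 4.0)])
        assert np.allclose(dff.dff[:500], 0.0, atol=1e-9)
        assert np.median(dff.dff[500:]) > 10.0


class TestAlignTrials:
    def test_constant_trace_aligns_to_zero(self):
        dff = make_dff(np.full(1000, 7.0))
        trials = TrialTable(onset_times=[40.0, 60.0], labels=None)
        out = align_trials(dff, trials, window=(-10, 20))
        assert out.traces.shape[0] == 2
        assert np.allclose(out.traces, 0.0)

    def test_injected_step_height_recovered(self):
        x = np.zeros(2000)
        x[1000:] = 5.0
        dff = make_dff(x, fs=10.0)
        out = align_trials(dff, TrialTable(onset_times=[100.0], labels=None),
                           window=(-10, 20))
        post = out.traces[0][out.rel_time > 0]
        assert post.mean() == pytest.approx(5.0, abs=1e-9)

    def test_edge_trials_excluded_and_counted(self):
        dff = make_dff(np.zeros(500))
        trials = TrialTable(onset_times=[2.0, 25.0, 49.5], labels=None)
        out = align_trials(dff, trials, window=(-10, 20))
        assert out.n_excluded == 2
        assert out.traces.shape[0] == 1


class TestTransientMetrics:
    def test_unit_rectangle(self):
        t = np.arange(-5, 15, 0.01)
        y = ((t >= 1) & (t < 3)).astype(float)
        m = transient_metrics(t, y, quant_window=(0, 10))
        assert m.peak == pytest.approx(1.0)
        assert m.auc == pytest.approx(2.0, abs=0.02)

    def test_zero_trace(self):
        t = np.arange(-5, 15, 0.1)
        m = transient_metrics(t, np.zeros_like(t), quant_window=(0, 10))
        assert m.peak == 0.0 and m.auc == 0.0

    def test_gaussian_bump_matches_analytic_integral(self):
        t = np.arange(-5, 15, 0.001)
        sigma, mu, amp = 0.8, 5.0, 3.0
        y = amp * np.exp(-((t - mu) ** 2) / (2 * sigma**2))
        m = transient_metrics(t, y, quant_window=(0, 10))
        expected = amp * sigma * np.sqrt(2 * np.pi)  # tails outside (0,10) negligible
        assert m.auc == pytest.approx(expected, rel=1e-3)


class TestOffDecay:
    @pytest.mark.parametrize("tau", [0.1, 0.5, 2.0, 8.0, 20.0])
    def test_single_exponential_mean_lifetime(self, tau):
        t = np.arange(0, 8 * tau, tau / 50)
        out = off_decay_time(t, np.exp(-t / tau), 0)
        assert out == pytest.approx(tau, rel=0.02)

    def test_flat_trace_is_undefined(self):
        t = np.arange(0, 10, 0.1)
        assert np.isnan(off_decay_time(t, np.full_like(t, 2.0), 0))

    def test_two_component_decay_matches_root_finding_oracle(self):
        t = np.arange(0, 40, 0.02)
        y = 0.5 * np.exp(-t / 1.0) + 0.5 * np.exp(-t / 5.0)
        target = y[0] / np.e
        oracle = optimize.brentq(
            lambda tt: 0.5 * np.exp(-tt / 1.0) + 0.5 * np.exp(-tt / 5.0) - target,
            0.0, 40.0)
        assert off_decay_time(t, y, 0) == pytest.approx(oracle, rel=0.02)


class TestVehicleNormalization:
    def test_simple_ratios(self):
        out = normalize_to_vehicle([2.0, 1.0], [1.0, 1.0, 1.0])
        np.testing.assert_allclose(out, [2.0, 1.0])

    def test_matches_direct_formula(self, rng):
        drug = rng.uniform(0.5, 3.0, 10)
        veh = rng.uniform(0.5, 2.0, 5)
        np.testing.assert_allclose(normalize_to_vehicle(drug, veh), drug / veh.mean())

    def test_nonpositive_vehicle_mean_rejected(self):
        with pytest.raises(NonPositiveBaselineError):
            normalize_to_vehicle([1.0], [-1.0, 0.5])


class TestStableWindow:
    def test_constant_plateau_spans_search_range(self):
        times = np.arange(5.0, 70.0, 5.0)
        w = stable_window(times, np.full(times.size, 3.0))
        assert (w.start, w.end) == (5.0, 65.0)
        assert w.duration == 60.0

    def test_plateau_then_decline_gives_thirty_minutes(self):
        times = np.arange(5.0, 70.0, 5.0)
        peaks = np.where(times <= 35.0, 3.0,
                         3.0 * (0.9 - 0.1 * (times - 35.0) / 5.0))
        w = stable_window(times, peaks)
        assert (w.start, w.end) == (5.0, 35.0)
        assert w.duration == 30.0
        assert w.plateau_level == pytest.approx(3.0)

    def test_boundary_value_is_included(self):
        times = np.arange(5.0, 35.0, 5.0)
        peaks = np.full(times.size, 2.0)
        peaks[-1] = 2.0 * 0.85  # exactly at the closed-interval edge
        w = stable_window(times, peaks, plateau_trials=(5.0, 10.0, 15.0, 20.0))
        assert w.end == 30.0

    def test_out_of_tolerance_first_trial_flags_empty(self):
        times = np.arange(5.0, 40.0, 5.0)
        peaks = np.full(times.size, 3.0)
        peaks[0] = 1.0
        # plateau from later trials; first search trial outside tolerance
        w = stable_window(times, peaks, plateau_trials=(10.0, 15.0, 20.0))
        assert w.empty and w.duration == 0.0

    @pytest.mark.parametrize("tight,loose", [(0.05, 0.15), (0.10, 0.30)])
    def test_duration_monotone_in_tolerance(self, rng, tight, loose):
        times = np.arange(5.0, 70.0, 5.0)
        peaks = 3.0 + np.cumsum(rng.normal(0, 0.15, times.size))
        w_tight = stable_window(times, peaks, tolerance=tight)
        w_loose = stable_window(times, peaks, tolerance=loose)
        assert w_tight.duration <= w_loose.duration


class TestSpontaneousPeaks:
    def test_flat_trace_has_no_peaks(self):
        assert len(detect_spontaneous_peaks(make_dff(np.zeros(1000), fs=122.0))) == 0

    def test_two_triangles_detected(self):
        x = np.zeros(3000)
        for c in (1000, 2000):
            x[c - 100:c] = np.linspace(0, 1.0, 100)
            x[c:c + 100] = np.linspace(1.0, 0, 100)
        out = detect_spontaneous_peaks(make_dff(x, fs=122.0), min_prominence=0.5)
        assert len(out) == 2
        # the 410 ms moving average trims the triangle apex but keeps prominence high
        assert (out["prominence"] > 0.8).all()

    def test_subthreshold_prominence_rejected(self):
        x = np.zeros(2000)
        x[900:1000] = np.linspace(0, 0.4, 100)
        x[1000:1100] = np.linspace(0.4, 0, 100)
        out = detect_spontaneous_peaks(make_dff(x, fs=122.0), min_prominence=0.5)
        assert len(out) == 0

    def test_count_invariant_to_constant_offset(self, rng):
        x = np.convolve(rng.normal(0, 0.5, 5000), np.ones(20) / 20, mode="same")
        a = detect_spontaneous_peaks(make_dff(x, fs=122.0))
        b = detect_spontaneous_peaks(make_dff(x + 42.0, fs=122.0))
        assert len(a) == len(b)


class TestLongformBleach:
    def _cubic(self, t):
        return 100 - 0.01 * t + 1e-5 * t**2 - 2e-9 * t**3

    def test_shared_cubic_cancels(self):
        t = np.arange(0, 600, 0.1)
        c = self._cubic(t)
        rec = PhotometryRecording(time=t, reference=c, signal=c, fs=10.0)
        assert np.allclose(longform_bleach_correct(rec).dff, 0.0, atol=1e-9)

    def test_tonic_bump_on_signal_channel_recovered(self):
        # a bump occupying a small fraction of the span is barely absorbed
        # by the cubic bleach fit, so its contrast survives the correction
        t = np.arange(0, 6000, 0.1)
        c = 100 - 0.005 * t + 5e-7 * t**2 - 2e-11 * t**3
        bump = 1 + 0.1 * ((t > 3000) & (t < 3150))
        rec = PhotometryRecording(time=t, reference=c, signal=c * bump, fs=10.0)
        dff = longform_bleach_correct(rec)
        inside = (t > 3010) & (t < 3140)
        outside = (t > 200) & (t < 2800)
        contrast = np.median(dff.dff[inside]) - np.median(dff.dff[outside])
        assert contrast == pytest.approx(10.0, abs=1.5)

    def test_normalized_channels_have_unit_mean(self, rng):
        t = np.arange(0, 600, 0.1)
        rec = PhotometryRecording(time=t, reference=self._cubic(t) + rng.normal(0, 0.5, t.size),
                                  signal=self._cubic(t) + rng.normal(0, 0.5, t.size),
                                  fs=10.0)
        dff = longform_bleach_correct(rec)
        assert abs(dff.dff.mean()) < 0.1  # both channels divided by their own fit


class TestTonicBaseline:
    def test_zero_trace_zero_auc(self):
        dff = make_dff(np.zeros(60000), fs=20.0)  # 50 min
        _, auc = tonic_baseline(dff, auc_window_min=(5, 40))
        assert auc == 0.0

    def test_step_auc_matches_construction(self):
        fs = 20.0
        n = int(50 * 60 * fs)
        x = np.zeros(n)
        t = np.arange(n) / fs
        x[t >= 120.0] = 20.0  # injection at t=120 s
        dff = DffTrace(time=t, dff=x, fs=fs)
        _, auc = tonic_baseline(dff, median_window_s=82.0, auc_window_min=(5, 40),
                                injection_time_s=120.0)
        assert auc == pytest.approx(20.0 * 35 * 60, rel=0.01)

    def test_median_ignores_sparse_impulses(self, rng):
        fs = 20.0
        x = np.zeros(int(10 * 60 * fs))
        idx = rng.choice(x.size, 30, replace=False)
        x[idx] = 50.0
        baseline, _ = tonic_baseline(make_dff(x, fs=fs), median_window_s=30.0,
                                     auc_window_min=(0.5, 5.0))
        assert np.abs(baseline.dff).max() == 0.0
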