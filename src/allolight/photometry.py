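"""Single-fiber photometry analysis.

Implements the full in vivo pipeline for two-channel recordings: zero-phase
low-pass filtering and downsampling, isosbestic-corrected ΔF/F0 (the
ligand-insensitive 405 nm channel is linearly rescaled onto the 465 nm
channel and used as F0), trial alignment and transient metrics, the
double-exponential off-decay mean lifetime (1/e rule), vehicle
normalization, the plateau "stable imaging window" algorithm,
prominence-based spontaneous peak detection, and the long-recording branch
(per-channel polynomial bleach correction + moving-median tonic baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.optimize import least_squares

from .errors import FitConvergenceError, NonPositiveBaselineError

__all__ = [
    "PhotometryRecording",
    "DffTrace",
    "TrialTable",
    "TransientMetrics",
    "StableWindow",
    "AlignedTrials",
    "preprocess",
    "compute_dff",
    "align_trials",
    "transient_metrics",
    "off_decay_time",
    "normalize_to_vehicle",
    "stable_window",
    "detect_spontaneous_peaks",
    "longform_bleach_correct",
    "tonic_baseline",
]


@dataclass(frozen=True)
class PhotometryRecording:
    """Uniformly sampled two-channel recording (405 nm reference, 465 nm signal)."""

    time: np.ndarray
    reference: np.ndarray
    signal: np.ndarray
    fs: float

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.reference, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if not (t.shape == r.shape == s.shape) or t.ndim != 1:
            raise ValueError("time, reference and signal must be equal-length 1-D")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-6 * max(1.0, 1.0 / self.fs):
                raise ValueError("time grid is not uniform at the declared fs")
        for name, arr in (("time", t), ("reference", r), ("signal", s)):
            object.__setattr__(self, name, arr)

    @property
    def n_samples(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class DffTrace:
    """ΔF/F0 trace in percent on a uniform time grid."""

    time: np.ndarray
    dff: np.ndarray
    fs: float

    def __post_init__(self):
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "dff", np.asarray(self.dff, dtype=float))


@dataclass(frozen=True)
class TrialTable:
    """Trial onsets (seconds, sorted) with condition labels."""

    onset_times: np.ndarray
    labels: tuple

    def __post_init__(self):
        t = np.asarray(self.onset_times, dtype=float)
        labels = tuple(self.labels) if self.labels is not None else ("",) * t.size
        if len(labels) != t.size:
            raise ValueError("labels must match onset_times")
        if np.any(np.diff(t) < 0):
            order = np.argsort(t, kind="stable")
            t = t[order]
            labels = tuple(labels[i] for i in order)
        object.__setattr__(self, "onset_times", t)
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class TransientMetrics:
    peak: float            # percent ΔF/F0
    auc: float             # percent * seconds over the quantification window
    off_decay: float = float("nan")  # seconds (NaN = undefined)


@dataclass(frozen=True)
class StableWindow:
    """Contiguous post-drug interval where peaks stay within tolerance of the plateau."""

    start: float      # minutes post-drug
    end: float
    plateau_level: float
    empty: bool = False

    @property
    def duration(self) -> float:
        return 0.0 if self.empty else self.end - self.start


@dataclass(frozen=True)
class AlignedTrials:
    """Per-trial baseline-corrected segments on a shared relative time grid."""

    rel_time: np.ndarray          # seconds relative to onset
    traces: np.ndarray            # (n_included, n_samples)
    onsets: np.ndarray            # included trial onsets
    labels: tuple
    n_excluded: int = 0


def preprocess(rec: PhotometryRecording, downsample_factor: int = 10,
               lowpass_hz: float | None = 2.0) -> PhotometryRecording:
    """Zero-phase low-pass filter both channels, then decimate by block averaging.

    The cutoff must stay below the post-decimation Nyquist frequency.
    """
    if downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    new_fs = rec.fs / downsample_factor
    if lowpass_hz is not None and lowpass_hz >= new_fs / 2:
        raise ValueError(
            f"lowpass {lowpass_hz} Hz is above the new Nyquist {new_fs / 2:g} Hz")

    ref, sig = rec.reference, rec.signal
    if lowpass_hz is not None:
        sos = signal.butter(2, lowpass_hz, btype="low", fs=rec.fs, output="sos")
        ref = signal.sosfiltfilt(sos, ref)
        sig = signal.sosfiltfilt(sos, sig)
    if downsample_factor > 1:
        n = (rec.n_samples // downsample_factor) * downsample_factor
        ref = ref[:n].reshape(-1, downsample_factor).mean(axis=1)
        sig = sig[:n].reshape(-1, downsample_factor).mean(axis=1)
        time = rec.time[:n].reshape(-1, downsample_factor).mean(axis=1)
    else:
        time = rec.time
    return PhotometryRecording(time=time, reference=ref, signal=sig, fs=new_fs)


def _scope_mask(rec: PhotometryRecording, fit_scope) -> np.ndarray:
    """Boolean sample mask for the isosbestic fit scope.

    ``fit_scope`` is None/"whole" (entire recording), a boolean mask, or a
    list of ``(start_s, end_s)`` windows (e.g. -60..+60 s around each opto
    event, or -5..-1 s before behavioral events).
    """
    if fit_scope is None or (isinstance(fit_scope, str) and fit_scope == "whole"):
        return np.ones(rec.n_samples, dtype=bool)
    arr = np.asarray(fit_scope)
    if arr.dtype == bool:
        if arr.shape != rec.time.shape:
            raise ValueError("boolean fit_scope must match the recording length")
        return arr
    mask = np.zeros(rec.n_samples, dtype=bool)
    for start, end in fit_scope:
        if end < rec.time[0] or start > rec.time[-1]:
            raise ValueError(f"scope window ({start}, {end}) outside the recording")
        mask |= (rec.time >= start) & (rec.time <= end)
    if not mask.any():
        raise ValueError("fit scope selects no samples")
    return mask


def compute_dff(rec: PhotometryRecording, fit_scope=None) -> DffTrace:
    """Isosbestic-corrected ΔF/F0 (percent).

    A least-squares linear fit rescales the 405 nm reference onto the 465 nm
    signal over the scope samples (``fitted = a*reference + b``); F0 is the
    fitted reference and ``dff = (signal - fitted)/fitted * 100`` over the
    whole recording.
    """
    mask = _scope_mask(rec, fit_scope)
    a, b = np.polyfit(rec.reference[mask], rec.signal[mask], 1)
    fitted = a * rec.reference + b
    if np.any(fitted <= 0):
        raise NonPositiveBaselineError("fitted reference is non-positive in the span")
    dff = (rec.signal - fitted) / fitted * 100.0
    return DffTrace(time=rec.time, dff=dff, fs=rec.fs)


def align_trials(dff: DffTrace, trials: TrialTable, window: tuple[float, float] = (-10.0, 60.0),
                 baseline_window: tuple[float, float] = (-10.0, -1.0)) -> AlignedTrials:
    """Extract per-trial segments and subtract each trial's pre-onset baseline.

    The baseline is the mean ΔF/F0 over ``baseline_window`` (default -10..-1 s)
    relative to onset.  Trials whose window falls outside the recording are
    excluded and counted, never zero-padded.
    """
    pre, post = window
    if pre >= post:
        raise ValueError("window must be (pre, post) with pre < post")
    n_pre = int(round(-pre * dff.fs))
    n_post = int(round(post * dff.fs))
    rel_time = np.arange(-n_pre, n_post + 1) / dff.fs

    t0 = dff.time[0]
    traces, onsets, labels = [], [], []
    n_excluded = 0
    for onset, label in zip(trials.onset_times, trials.labels):
        i0 = int(round((onset - t0) * dff.fs))
        lo, hi = i0 - n_pre, i0 + n_post + 1
        if lo < 0 or hi > dff.dff.size:
            n_excluded += 1
            continue
        seg = dff.dff[lo:hi].copy()
        bmask = (rel_time >= baseline_window[0]) & (rel_time <= baseline_window[1])
        if bmask.any():
            seg -= seg[bmask].mean()
        traces.append(seg)
        onsets.append(onset)
        labels.append(label)
    traces = np.array(traces) if traces else np.empty((0, rel_time.size))
    return AlignedTrials(rel_time=rel_time, traces=traces, onsets=np.array(onsets),
                         labels=tuple(labels), n_excluded=n_excluded)


def transient_metrics(rel_time, trace, quant_window: tuple[float, float] = (0.0, 10.0),
                      compute_decay: bool = False) -> TransientMetrics:
    """Peak and trapezoidal AUC of an aligned trace over the quantification window."""
    rel_time = np.asarray(rel_time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    lo, hi = quant_window
    mask = (rel_time >= lo) & (rel_time <= hi)
    if not mask.any():
        raise ValueError("quantification window outside the aligned span")
    peak = float(trace[mask].max())
    auc = float(np.trapezoid(trace[mask], rel_time[mask]))
    off = float("nan")
    if compute_decay:
        peak_idx = int(np.flatnonzero(mask)[np.argmax(trace[mask])])
        off = off_decay_time(rel_time, trace, peak_idx)
    return TransientMetrics(peak=peak, auc=auc, off_decay=off)


def _double_exp(t, a1, tau1, a2, dtau):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / (tau1 + dtau))


def off_decay_time(time, trace, peak_index: int) -> float:
    """Mean lifetime of a transient: 1/e crossing of a double-exponential fit.

    ``y(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2)`` is fitted from the peak
    (amplitudes >= 0, tau2 >= tau1 > 0, no offset); the returned time is the
    first point where the fitted curve falls below 36.8% (1/e) of its
    maximum, found by bisection.  Returns NaN when the fit does not converge
    or the fitted curve never crosses within the trace span ("undefined
    decay").
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    t = time[peak_index:] - time[peak_index]
    y = trace[peak_index:]
    if t.size < 20:
        raise ValueError("need >= 20 samples after the peak")
    span = t[-1]
    y0 = y[0]
    if y0 <= 0:
        return float("nan")

    x0 = np.array([y0 / 2, 0.1 * span, y0 / 2, 0.4 * span])
    lo = [0.0, 1e-9, 0.0, 0.0]
    hi = [np.inf, np.inf, np.inf, np.inf]
    sol = least_squares(lambda p: _double_exp(t, *p) - y, x0, bounds=(lo, hi),
                        xtol=1e-13, ftol=1e-13, max_nfev=2000)
    if not sol.success:
        return float("nan")
    p = sol.x
    target = _double_exp(0.0, *p) * math.exp(-1.0)

    f = lambda tt: _double_exp(tt, *p) - target
    if f(span) > 0:  # never crosses within the observed span
        return float("nan")
    a, b = 0.0, span
    for _ in range(200):
        mid = 0.5 * (a + b)
        if f(mid) > 0:
            a = mid
        else:
            b = mid
        if b - a < 1e-12 * max(span, 1.0):
            break
    return float(0.5 * (a + b))


def normalize_to_vehicle(trial_peaks, vehicle_peaks) -> np.ndarray:
    """Divide each trial peak by the mean vehicle-trial peak."""
    veh = np.asarray(vehicle_peaks, dtype=float)
    if veh.size < 1:
        raise ValueError("need >= 1 vehicle trial")
    m = veh.mean()
    if m <= 0:
        raise NonPositiveBaselineError("mean vehicle peak is <= 0")
    return np.asarray(trial_peaks, dtype=float) / m


def stable_window(trial_times_min, normalized_peaks, plateau_trials=(5.0, 10.0, 15.0, 20.0),
                  tolerance: float = 0.15,
                  search_range: tuple[float, float] = (5.0, 65.0)) -> StableWindow:
    """Temporal window for stable imaging.

    The plateau level is the mean normalized peak at ``plateau_trials``
    (minutes post-drug).  Trials within ``search_range`` are scanned in
    order; the window is the maximal contiguous run starting at the first
    in-range trial whose peaks stay within ``plateau*(1 +/- tolerance)``
    (closed interval).  If the first in-range trial is already outside
    tolerance the window is empty and flagged.
    """
    t = np.asarray(trial_times_min, dtype=float)
    p = np.asarray(normalized_peaks, dtype=float)
    order = np.argsort(t, kind="stable")
    t, p = t[order], p[order]

    plateau_vals = []
    for pt in plateau_trials:
        i = np.flatnonzero(np.isclose(t, pt))
        if i.size == 0:
            raise ValueError(f"plateau trial at {pt} min not in the series")
        plateau_vals.append(p[i[0]])
    plateau = float(np.mean(plateau_vals))

    in_range = (t >= search_range[0]) & (t <= search_range[1])
    ts, ps = t[in_range], p[in_range]
    if ts.size == 0:
        raise ValueError("no trials inside the search range")
    ok = np.abs(ps - plateau) <= tolerance * plateau + 1e-12
    if not ok[0]:
        return StableWindow(start=float(ts[0]), end=float(ts[0]),
                            plateau_level=plateau, empty=True)
    last = 0
    while last + 1 < ts.size and ok[last + 1]:
        last += 1
    return StableWindow(start=float(ts[0]), end=float(ts[last]), plateau_level=plateau)


def detect_spontaneous_peaks(dff: DffTrace, smooth_window_s: float = 0.41,
                             min_prominence: float = 0.5) -> pd.DataFrame:
    """Spontaneous transient detection on a smoothed ΔF/F0 trace.

    The trace is smoothed with a centered moving average (window rounded to
    the nearest odd sample count) and local maxima with topographic
    prominence >= ``min_prominence`` (% ΔF/F0) are returned as a table with
    columns ``time_s`` and ``peak_dff``.
    """
    n = int(round(smooth_window_s * dff.fs))
    n = max(3, n + 1 if n % 2 == 0 else n)
    kernel = np.ones(n) / n
    padded = np.pad(dff.dff, n // 2, mode="edge")
    smooth = np.convolve(padded, kernel, mode="valid")
    idx, props = signal.find_peaks(smooth, prominence=min_prominence)
    return pd.DataFrame({"time_s": dff.time[idx], "peak_dff": smooth[idx],
                         "prominence": props["prominences"]})


def longform_bleach_correct(rec: PhotometryRecording, poly_degree: int = 3) -> DffTrace:
    """Bleach-corrected ΔF/F0 for recordings lasting tens of minutes to hours.

    Each channel is divided by its own degree-``poly_degree`` least-squares
    polynomial fit (capturing photobleaching); ΔF/F0 is the difference of
    the normalized 465 and 405 nm channels, in percent.
    """
    x = rec.time - rec.time[0]
    out = {}
    for name, y in (("signal", rec.signal), ("reference", rec.reference)):
        coef = np.polynomial.polynomial.polyfit(x, y, poly_degree)
        fit = np.polynomial.polynomial.polyval(x, coef)
        if np.any(fit <= 0):
            raise NonPositiveBaselineError(
                f"degree-{poly_degree} fit of the {name} channel crosses zero")
        out[name] = y / fit
    dff = (out["signal"] - out["reference"]) * 100.0
    return DffTrace(time=rec.time, dff=dff, fs=rec.fs)


def tonic_baseline(dff: DffTrace, median_window_s: float = 82.0,
                   auc_window_min: tuple[float, float] = (5.0, 40.0),
                   injection_time_s: float = 0.0):
    """Moving-median tonic baseline and its AUC around a drug injection.

    Returns ``(baseline, auc)`` where ``baseline`` is a :class:`DffTrace`
    holding the running median (window rounded to the nearest odd sample
    count) and ``auc`` is its trapezoidal integral (percent*seconds) over
    ``auc_window_min`` minutes relative to ``injection_time_s``.
    """
    n = int(round(median_window_s * dff.fs))
    n = max(3, n + 1 if n % 2 == 0 else n)
    med = (pd.Series(dff.dff).rolling(n, center=True, min_periods=1)
           .median().to_numpy())
    baseline = DffTrace(time=dff.time, dff=med, fs=dff.fs)

    lo = injection_time_s + auc_window_min[0] * 60.0
    hi = injection_time_s + auc_window_min[1] * 60.0
    tol = 1.0 / dff.fs  # allow the window edge to fall within the last sample
    if lo < dff.time[0] - tol or hi > dff.time[-1] + tol:
        raise ValueError("AUC window outside the recording")
    mask = (dff.time >= lo) & (dff.time <= hi)
    auc = float(np.trapezoid(med[mask], dff.time[mask]))
    return baseline, auc
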