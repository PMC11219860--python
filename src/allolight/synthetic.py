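"""Seeded generators for every input the analysis stages consume.

Each generator implements a forward model with the statistical structure the
analyses assume — sigmoidal titration families under an allosteric shift,
two-channel photometry with photobleaching, shared motion artifacts,
PK-driven tonic steps and kernel-shaped phasic transients, sniffer-cell ROI
grids with Poisson release events, and multi-region sessions with
region-specific tonic oscillation scales — and returns the generated data
together with the ground truth needed to score the downstream stage.

Tonic, phasic and motion terms compose multiplicatively on top of the
per-channel bleach envelope (i.e. in the ΔF/F domain), so the isosbestic
correction is exactly solvable in the noiseless limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .dose_response import AllostericParams, TitrationCurve, TitrationFamily, four_pl, \
    predict_shifted_ec50
from .multifiber import SessionTrace
from .photometry import PhotometryRecording, TrialTable
from .pk import DETQ_IP_PROFILE, PKProfile, interpolate_pk, occupancy

__all__ = [
    "SessionSpec",
    "GroundTruth",
    "DEFAULT_MODULATOR_GRID",
    "transient_kernel",
    "simulate_titration_family",
    "simulate_photometry_session",
    "simulate_sniffer_rois",
    "simulate_multifiber",
]

# modulator concentrations used in the titration experiments (molar)
DEFAULT_MODULATOR_GRID = tuple(b * 1e-9 for b in (0, 1, 5, 10, 20, 50, 150, 450))


@dataclass
class GroundTruth:
    """True generating quantities recorded alongside every synthetic dataset."""

    params: dict = field(default_factory=dict)
    event_times: dict = field(default_factory=dict)
    event_amplitudes: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SessionSpec:
    """Forward-model settings for a two-channel photometry session.

    Defaults mirror the in vivo single-fiber design: 1017.3 Hz acquisition,
    optogenetic trials every 5 min, a PK-driven tonic step after an i.p.
    injection, slow double-exponential photobleaching, a shared low-frequency
    motion artifact and white measurement noise.  Transient kernels are
    difference-of-exponentials with rise 0.2 s and decay 1.5 s.
    """

    duration_s: float = 3600.0
    fs: float = 1017.3
    injection_time_s: float = 600.0
    tonic_step_pct: float = 20.0
    pk_profile: PKProfile = DETQ_IP_PROFILE
    pk_kb_M: float = 54e-9
    transient_times_s: tuple = tuple(float(t) for t in range(900, 3600, 300))
    transient_amp_pct: float = 5.0
    tau_rise_s: float = 0.2
    tau_decay_s: float = 1.5
    motion_pct: float = 1.0
    noise_sd: float = 0.5
    bleach_taus_s: tuple = (1500.0, 12000.0)
    bleach_frac: float = 0.3
    f465: float = 100.0
    f405: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration must be > 0")
        if not self.tau_decay_s > self.tau_rise_s > 0:
            raise ValueError("need tau_decay > tau_rise > 0")


def transient_kernel(t, amp: float, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials release kernel normalized to peak ``amp``."""
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                   - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = np.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)
    norm = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return amp * raw / norm


def simulate_titration_family(params: AllostericParams,
                              modulator_grid=DEFAULT_MODULATOR_GRID,
                              n_points: int = 9, noise_cv: float = 0.05,
                              seed: int = 0):
    """Synthetic DA titration family under increasing modulator concentrations.

    Responses follow the 4PL forward model with each curve's midpoint given
    by the allosteric shift; multiplicative lognormal noise of coefficient
    of variation ``noise_cv`` is applied.  Concentrations span two decades
    around the shifted-midpoint range so every curve covers its own
    inflection.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    lo = np.log10(params.ec50 / params.alpha) - 1.5
    hi = np.log10(params.ec50) + 1.5
    conc = 10.0 ** np.linspace(lo, hi, n_points)

    curves = []
    for b in modulator_grid:
        ec50_star = predict_shifted_ec50(params, b)
        resp = four_pl(conc, params.bottom, params.top, ec50_star, params.hill)
        if sigma > 0:
            resp = resp * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=resp.shape))
        curves.append(TitrationCurve(concentrations=conc, responses=resp,
                                     modulator_conc=float(b)))
    truth = GroundTruth(params={"ec50": params.ec50, "kb": params.kb,
                                "alpha": params.alpha, "top": params.top,
                                "bottom": params.bottom, "hill": params.hill})
    return TitrationFamily(curves=tuple(curves)), truth


def _smooth_noise(rng, n, fs, cutoff_hz=0.3):
    """Unit-RMS low-frequency noise (shared motion artifact shape)."""
    x = rng.standard_normal(n)
    if n > 30:
        sos = sps.butter(2, min(cutoff_hz, 0.45 * fs), btype="low", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def simulate_photometry_session(spec: SessionSpec):
    """Two-channel photometry session with known tonic and phasic ground truth.

    The 465 nm channel carries the dopamine-dependent terms (tonic step and
    transients); the motion artifact is shared with the 405 nm reference::

        signal    = bleach465(t) * [1 + (tonic + transients + motion)/100] + noise
        reference = bleach405(t) * [1 + motion/100] + noise

    The tonic step follows receptor occupancy of the PK profile, scaled so
    its maximum equals ``tonic_step_pct``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    time = np.arange(n) / spec.fs

    tau1, tau2 = spec.bleach_taus_s
    env = (1 - spec.bleach_frac) + spec.bleach_frac * (
        0.5 * np.exp(-time / tau1) + 0.5 * np.exp(-time / tau2))
    bleach465 = spec.f465 * env
    bleach405 = spec.f405 * env

    tonic = np.zeros(n)
    post = time >= spec.injection_time_s
    if post.any() and spec.tonic_step_pct != 0:
        t_min = (time[post] - spec.injection_time_s) / 60.0
        occ = occupancy(interpolate_pk(spec.pk_profile, t_min), spec.pk_kb_M)
        peak = occ.max()
        if peak > 0:
            tonic[post] = spec.tonic_step_pct * occ / peak

    phasic = np.zeros(n)
    for t_ev in spec.transient_times_s:
        phasic += transient_kernel(time - t_ev, spec.transient_amp_pct,
                                   spec.tau_rise_s, spec.tau_decay_s)

    motion = spec.motion_pct * _smooth_noise(rng, n, spec.fs) if spec.motion_pct else np.zeros(n)

    sig = bleach465 * (1 + (tonic + phasic + motion) / 100.0)
    ref = bleach405 * (1 + motion / 100.0)
    if spec.noise_sd > 0:
        sig = sig + rng.normal(0, spec.noise_sd, n)
        ref = ref + rng.normal(0, spec.noise_sd, n)

    rec = PhotometryRecording(time=time, reference=ref, signal=sig, fs=spec.fs)
    trials = TrialTable(onset_times=np.asarray(spec.transient_times_s, dtype=float),
                        labels=("opto",) * len(spec.transient_times_s))
    truth = GroundTruth(
        params={"tonic_step_pct": spec.tonic_step_pct,
                "transient_amp_pct": spec.transient_amp_pct,
                "injection_time_s": spec.injection_time_s},
        event_times={"opto": np.asarray(spec.transient_times_s, dtype=float)},
        event_amplitudes={"opto": np.full(len(spec.transient_times_s),
                                          spec.transient_amp_pct)},
    )
    return rec, trials, truth


def simulate_sniffer_rois(n_rois: int = 16, frame_interval: float = 0.6,
                          duration_s: float = 600.0, hotspot_rois=(2, 5, 10),
                          event_rate_pre: float = 0.005, event_rate_post: float = 0.02,
                          modulator_onset_s: float = 300.0, tonic_step_post: float = 10.0,
                          event_amp_sd: float = 8.0, noise_sd: float = 1.0,
                          baseline: float = 100.0, tau_rise_s: float = 0.2,
                          tau_decay_s: float = 1.5, seed: int = 0):
    """Sniffer-cell ROI traces with localized Poisson release events.

    Hotspot ROIs receive kernel-shaped events at ``event_rate_pre`` /
    ``event_rate_post`` (Hz) before/after the modulator onset, every ROI
    gains a tonic baseline step of ``tonic_step_post`` (raw units) after the
    onset, and Gaussian noise of SD ``noise_sd`` is added.  Event peak
    amplitudes are ``event_amp_sd`` times the noise SD.  Returns
    ``(traces, truth)`` where ``traces`` is (n_frames, n_rois).
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s / frame_interval))
    time = np.arange(n_frames) * frame_interval
    traces = np.full((n_frames, n_rois), baseline)

    post = time >= modulator_onset_s
    traces[post, :] += tonic_step_post

    event_times = {}
    amp = event_amp_sd * noise_sd
    for roi in hotspot_rois:
        times = []
        for (t0, t1, rate) in ((0.0, modulator_onset_s, event_rate_pre),
                               (modulator_onset_s, duration_s, event_rate_post)):
            n_ev = rng.poisson(rate * (t1 - t0))
            times.extend(rng.uniform(t0, t1, n_ev))
        times = np.sort(np.array(times))
        event_times[roi] = times
        for t_ev in times:
            traces[:, roi] += transient_kernel(time - t_ev, amp, tau_rise_s, tau_decay_s)

    if noise_sd > 0:
        traces = traces + rng.normal(0, noise_sd, traces.shape)

    truth = GroundTruth(
        params={"tonic_step_post": tonic_step_post, "event_amp": amp,
                "modulator_onset_s": modulator_onset_s,
                "hotspot_rois": tuple(hotspot_rois)},
        event_times=event_times,
    )
    return traces, truth


_DEFAULT_REGIONS = (
    {"label": "NAc", "scale_s": 15.0, "amp_pre": 0.3, "amp_post": 2.0, "peak_pct": 22.3},
    {"label": "CPu", "scale_s": 10.0, "amp_pre": 0.3, "amp_post": 2.0, "peak_pct": 28.3},
    {"label": "PFC", "scale_s": 3.5, "amp_pre": 0.3, "amp_post": 2.0, "peak_pct": 6.8},
)


def simulate_multifiber(regions=_DEFAULT_REGIONS, channels_per_region: int = 4,
                        fs: float = 10.0, pre_s: float = 3600.0, post_s: float = 7200.0,
                        decay_tau_s: float = 2400.0, rise_s: float = 300.0,
                        noise_sd: float = 0.3, seed: int = 0):
    """Multi-region session with region-specific tonic oscillation scales.

    Each channel carries a narrowband oscillation at its region's temporal
    scale (amplitude boosted after the injection), a drug trend (linear rise
    to ``peak_pct`` then exponential decay with time constant
    ``decay_tau_s``), a mild pre-injection bleaching drift, and white noise.
    Region signatures default to the three recorded areas: ~15 s NAc, 10 s
    CPu and a phasic-like 3.5 s PFC component.
    """
    rng = np.random.default_rng(seed)
    n = int(round((pre_s + post_s) * fs))
    time = np.arange(n) / fs
    injection = pre_s

    dffs, labels = [], []
    truth_params = {"injection_time_s": injection, "decay_tau_s": decay_tau_s,
                    "regions": {}}
    for region in regions:
        truth_params["regions"][region["label"]] = dict(region)
        for _ in range(channels_per_region):
            trend = np.zeros(n)
            pre_mask = time < injection
            trend[pre_mask] = -0.5 * (time[pre_mask] / injection)  # slow bleach drift
            tp = time[~pre_mask] - injection
            rise = np.clip(tp / rise_s, 0, 1)
            trend[~pre_mask] = region["peak_pct"] * rise * np.exp(
                -np.maximum(tp - rise_s, 0) / decay_tau_s)

            phase = rng.uniform(0, 2 * np.pi)
            osc = np.sin(2 * np.pi * time / region["scale_s"] + phase)
            amp = np.where(time < injection, region["amp_pre"], region["amp_post"])
            dffs.append(trend + amp * osc + rng.normal(0, noise_sd, n))
            labels.append(region["label"])

    session = SessionTrace(time=time, dff=np.array(dffs), injection_time=injection,
                           region_labels=tuple(labels), fs=fs)
    return session, GroundTruth(params=truth_params)
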