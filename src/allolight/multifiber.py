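"""Multi-fiber (multi-region) photometry: trends, drug kinetics, wavelet scales.

The recording is split at the injection and each segment independently
detrended with a second-order polynomial; the post-injection trend carries
the drug effect (peak ΔF/F0 and the 1/e pharmacokinetic decay time).  The
detrended residuals are decomposed with a continuous wavelet transform over
temporal scales of 1-30 s, and per-scale mean magnitudes of matched pre/post
epochs are compared channel-wise with a Wilcoxon signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SessionTrace",
    "ScalePower",
    "TrendResult",
    "DrugEffect",
    "segment_trend",
    "drug_effect_metrics",
    "default_scale_grid",
    "scale_decomposition",
    "epoch_scale_analysis",
    "compare_epochs",
]


@dataclass(frozen=True)
class SessionTrace:
    """Multi-channel ΔF/F0 session with a known injection time."""

    time: np.ndarray                 # seconds
    dff: np.ndarray                  # (n_channels, n_samples) percent
    injection_time: float            # seconds
    region_labels: tuple             # per-channel tags, e.g. PFC/NAc/CPu
    fs: float

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        d = np.atleast_2d(np.asarray(self.dff, dtype=float))
        if d.shape[1] != t.size:
            raise ValueError("dff must be (n_channels, n_samples)")
        if not t[0] <= self.injection_time <= t[-1]:
            raise ValueError("injection_time outside the recording span")
        labels = tuple(self.region_labels)
        if len(labels) != d.shape[0]:
            raise ValueError("one region label per channel required")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "dff", d)
        object.__setattr__(self, "region_labels", labels)


@dataclass(frozen=True)
class ScalePower:
    """Mean wavelet-coefficient magnitude per temporal scale within one epoch."""

    scales_s: np.ndarray             # pseudo-period seconds, ascending
    power: np.ndarray                # (n_channels, n_scales), >= 0; NaN = masked

    def __post_init__(self):
        object.__setattr__(self, "scales_s", np.asarray(self.scales_s, dtype=float))
        object.__setattr__(self, "power", np.atleast_2d(np.asarray(self.power, dtype=float)))


@dataclass(frozen=True)
class TrendResult:
    time: np.ndarray
    trend: np.ndarray
    residual: np.ndarray


@dataclass(frozen=True)
class DrugEffect:
    peak: float                       # percent ΔF/F0, max of the post trend
    peak_time: float                  # seconds
    decay_s: float                    # first 1/e crossing after the peak
    censored: bool                    # True when the trend never reaches peak/e


def segment_trend(time, trace, injection_time: float, degree: int = 2):
    """Independent polynomial trends before and after the injection.

    Returns ``(pre, post)`` :class:`TrendResult` pairs holding the fitted
    trend and the detrended residual on each segment.
    """
    time = np.asarray(time, dtype=float)
    trace = np.asarray(trace, dtype=float)
    pre_mask = time < injection_time
    post_mask = ~pre_mask
    out = []
    for mask in (pre_mask, post_mask):
        t, y = time[mask], trace[mask]
        if t.size < degree + 1:
            raise ValueError("segment shorter than degree + 1 samples")
        x = t - t[0]  # local origin keeps the Vandermonde well-conditioned
        coef = np.polynomial.polynomial.polyfit(x, y, degree)
        trend = np.polynomial.polynomial.polyval(x, coef)
        out.append(TrendResult(time=t, trend=trend, residual=y - trend))
    return out[0], out[1]


def drug_effect_metrics(post: TrendResult, injection_time: float) -> DrugEffect:
    """Peak of the post-injection trend and its 1/e decay time.

    The decay time is the first post-peak time where the trend falls below
    ``peak/e``, minus the peak time; if the trend never crosses before the
    end of the recording the estimate is censored (lower bound reported).
    """
    i_peak = int(np.argmax(post.trend))
    peak = float(post.trend[i_peak])
    t_peak = float(post.time[i_peak])
    after = post.trend[i_peak:]
    below = np.flatnonzero(after < peak / np.e)
    if below.size == 0:
        return DrugEffect(peak=peak, peak_time=t_peak,
                          decay_s=float(post.time[-1] - t_peak), censored=True)
    # refine the crossing linearly between the bracketing samples
    j = i_peak + below[0]
    t1, t0 = post.time[j], post.time[j - 1]
    y1, y0 = post.trend[j], post.trend[j - 1]
    target = peak / np.e
    t_cross = t0 + (target - y0) / (y1 - y0) * (t1 - t0) if y1 != y0 else t1
    return DrugEffect(peak=peak, peak_time=t_peak,
                      decay_s=float(t_cross - t_peak), censored=False)


def default_scale_grid(n: int = 24, lo: float = 1.0, hi: float = 30.0) -> np.ndarray:
    """Logarithmically spaced temporal-scale grid (seconds)."""
    return np.geomspace(lo, hi, n)


def scale_decomposition(detrended, fs: float, scales_s=None,
                        wavelet: str = "cmor1.5-1.0") -> ScalePower:
    """Continuous-wavelet scale power of detrended ΔF/F0 within one epoch.

    Uses an analytic (complex Morlet) wavelet; the scale axis is expressed
    in pseudo-period seconds.  Scales longer than half the epoch are masked
    (NaN) and logged rather than reported.
    """
    x = np.atleast_2d(np.asarray(detrended, dtype=float))
    if scales_s is None:
        scales_s = default_scale_grid()
    scales_s = np.asarray(scales_s, dtype=float)
    freqs = 1.0 / scales_s
    wav_scales = pywt.frequency2scale(wavelet, freqs / fs)

    epoch_s = x.shape[1] / fs
    valid = scales_s <= epoch_s / 2.0
    if not valid.all():
        logger.warning("masking %d scale(s) longer than half the %.0f s epoch",
                       int((~valid).sum()), epoch_s)

    power = np.full((x.shape[0], scales_s.size), np.nan)
    if valid.any():
        coeffs, _ = pywt.cwt(x, wav_scales[valid], wavelet,
                             sampling_period=1.0 / fs, axis=-1)
        # coeffs: (n_scales, n_channels, n_samples)
        power[:, valid] = np.abs(coeffs).mean(axis=-1).T
    return ScalePower(scales_s=scales_s, power=power)


def epoch_scale_analysis(session: SessionTrace, pre_min: float = 30.0,
                         post_min: float = 30.0, blank_min: float = 5.0,
                         scales_s=None, degree: int = 2):
    """Detrended pre/post-injection scale power for every channel.

    Each channel is split at the injection and detrended per segment; the
    pre epoch is the last ``pre_min`` minutes before the injection and the
    post epoch starts after a ``blank_min``-minute blanking period (the
    baseline needs that long to reach its maximum) and lasts ``post_min``
    minutes.  Returns ``(pre_power, post_power)`` :class:`ScalePower` pairs.
    """
    t = session.time
    inj = session.injection_time
    pre_mask = (t >= inj - pre_min * 60.0) & (t < inj)
    post_mask = (t >= inj + blank_min * 60.0) & (t < inj + (blank_min + post_min) * 60.0)
    pre_res, post_res = [], []
    for ch in session.dff:
        pre_tr, post_tr = segment_trend(t, ch, inj, degree=degree)
        pre_res.append(pre_tr.residual[pre_mask[t < inj]])
        post_res.append(post_tr.residual[post_mask[t >= inj]])
    pre_power = scale_decomposition(np.array(pre_res), session.fs, scales_s)
    post_power = scale_decomposition(np.array(post_res), session.fs, scales_s)
    return pre_power, post_power


def compare_epochs(pre: ScalePower, post: ScalePower, alpha: float = 0.05,
                   bonferroni: bool = False):
    """Per-scale paired pre/post comparison across channels.

    Returns a dict with the per-scale mean paired difference (post - pre),
    the two-sided Wilcoxon signed-rank p-value (exact distribution for
    small channel counts; 1.0 by convention when all differences are zero),
    and a significance mask at ``alpha`` (optionally Bonferroni-corrected
    over scales).
    """
    if not np.allclose(pre.scales_s, post.scales_s):
        raise ValueError("pre/post scale grids must match")
    diffs = post.power - pre.power                  # (n_channels, n_scales)
    n_scales = diffs.shape[1]
    pvals = np.ones(n_scales)
    for j in range(n_scales):
        d = diffs[:, j]
        d = d[np.isfinite(d)]
        if d.size == 0 or np.all(d == 0):
            pvals[j] = 1.0
            continue
        method = "exact" if d.size < 25 else "auto"
        pvals[j] = stats.wilcoxon(d, zero_method="wilcox", method=method,
                                  alternative="two-sided").pvalue
    thresh = alpha / n_scales if bonferroni else alpha
    return {
        "scales_s": pre.scales_s,
        "mean_diff": np.nanmean(diffs, axis=0),
        "pvalue": pvals,
        "significant": pvals < thresh,
    }
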