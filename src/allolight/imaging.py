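"""Sniffer-cell and two-photon imaging quantification.

Covers ROI gridding of a field of view, the adaptive z-score event detector
(causal rolling mean/SD with an influence factor limiting how strongly
event frames update the running statistics), tonic-shift estimation, and
frame-based ΔF/F0 with supra-threshold area measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NonPositiveBaselineError

logger = logging.getLogger(__name__)

__all__ = [
    "RoiGrid",
    "DetectorParams",
    "grid_rois",
    "roi_means",
    "adaptive_threshold_events",
    "tonic_shift",
    "frame_dff",
    "supra_sigma_area",
]


@dataclass(frozen=True)
class RoiGrid:
    """Non-overlapping square ROIs tiling a field from the top-left origin."""

    boxes: tuple          # (row0, col0, side_px) per ROI
    side_px: int
    roi_size_um: float
    pixel_size_um: float


@dataclass(frozen=True)
class DetectorParams:
    """Adaptive z-score detector settings.

    ``window_s``: trailing window for the rolling mean/SD; ``influence``:
    weight in [0, 1] with which an event frame enters the filtered series
    (1 = raw rolling statistics, 0 = statistics frozen at the first event);
    ``k``: detection threshold in SD units.
    """

    window_s: float = 6.0
    influence: float = 0.2
    k: float = 5.0

    def __post_init__(self):
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if not 0.0 <= self.influence <= 1.0:
            raise ValueError("influence must be in [0, 1]")
        if self.k <= 0:
            raise ValueError("k must be > 0")


def grid_rois(field_size_px: tuple[int, int], pixel_size_um: float,
              roi_size_um: float = 55.0) -> RoiGrid:
    """Square ROI tiling of a (height, width) field; partial edge tiles dropped."""
    h, w = field_size_px
    side = int(round(roi_size_um / pixel_size_um))
    if side < 1:
        raise ValueError("ROI smaller than one pixel")
    if side > h or side > w:
        raise ValueError("ROI larger than the field")
    boxes = tuple((r * side, c * side, side)
                  for r in range(h // side) for c in range(w // side))
    return RoiGrid(boxes=boxes, side_px=side, roi_size_um=roi_size_um,
                   pixel_size_um=pixel_size_um)


def roi_means(stack: np.ndarray, grid: RoiGrid) -> np.ndarray:
    """Mean intensity per ROI per frame: (n_frames, n_rois) from a (T, H, W) stack."""
    out = np.empty((stack.shape[0], len(grid.boxes)))
    for j, (r0, c0, side) in enumerate(grid.boxes):
        out[:, j] = stack[:, r0:r0 + side, c0:c0 + side].mean(axis=(1, 2))
    return out


def adaptive_threshold_events(trace, frame_interval: float,
                              params: DetectorParams = DetectorParams()) -> pd.DataFrame:
    """Adaptive z-score event detection on one ROI trace.

    A causal (trailing-window) rolling mean ``m`` and SD ``s`` are computed
    on a filtered copy of the trace; frame ``t`` is supra-threshold when the
    raw sample exceeds ``m[t-1] + k*s[t-1]``.  Supra-threshold frames enter
    the filtered series as ``influence*x[t] + (1-influence)*filtered[t-1]``
    so large events only partially drag the running statistics upward.
    Consecutive supra-threshold frames merge into one event; the returned
    table has ``onset_s, duration_s, peak_amp`` (peak amplitude above the
    rolling mean at detection).  Detection starts once the warm-up window
    has non-zero variance.
    """
    x = np.asarray(trace, dtype=float)
    lag = max(2, int(round(params.window_s / frame_interval)))
    if x.size <= lag:
        raise ValueError("trace must be longer than the rolling window")

    filt = x.copy()
    flags = np.zeros(x.size, dtype=bool)
    mean = np.full(x.size, np.nan)
    sd = np.full(x.size, np.nan)
    mean[lag - 1] = filt[:lag].mean()
    sd[lag - 1] = filt[:lag].std(ddof=1)
    if sd[lag - 1] == 0:
        logger.warning("zero-variance warm-up window; detection disabled until "
                       "variance becomes positive")
    for t in range(lag, x.size):
        if sd[t - 1] > 0 and x[t] > mean[t - 1] + params.k * sd[t - 1]:
            flags[t] = True
            filt[t] = params.influence * x[t] + (1 - params.influence) * filt[t - 1]
        else:
            filt[t] = x[t]
        win = filt[t - lag + 1 : t + 1]
        mean[t] = win.mean()
        sd[t] = win.std(ddof=1)

    events = []
    t = lag
    while t < x.size:
        if flags[t]:
            start = t
            while t + 1 < x.size and flags[t + 1]:
                t += 1
            seg = x[start:t + 1] - mean[start - 1]
            events.append((start * frame_interval, (t - start + 1) * frame_interval,
                           float(seg.max())))
        t += 1
    return pd.DataFrame(events, columns=["onset_s", "duration_s", "peak_amp"])


def tonic_shift(trace_dff, pre_window: slice, post_window: slice) -> float:
    """Median ΔF/F0 difference between a post and a pre window (percent).

    The median makes the estimate robust to sparse phasic transients
    riding on the tonic level.
    """
    x = np.asarray(trace_dff, dtype=float)
    return float(np.median(x[post_window]) - np.median(x[pre_window]))


def frame_dff(frame_means, stim_index: int, baseline_frames: int = 10) -> np.ndarray:
    """Per-frame ΔF/F0 with F0 = mean of the frames immediately before the stimulus."""
    f = np.asarray(frame_means, dtype=float)
    if baseline_frames < 1 or baseline_frames > stim_index:
        raise ValueError("need 1 <= baseline_frames <= stim_index")
    f0 = f[stim_index - baseline_frames : stim_index].mean()
    if f0 <= 0:
        raise NonPositiveBaselineError(f"F0 = {f0:g} is non-positive")
    return (f - f0) / f0


def supra_sigma_area(dff_image, baseline_noise_sd: float, k: float = 2.0,
                     pixel_area_um2: float = 1.0) -> float:
    """Area (µm²) of the ΔF/F0 image exceeding ``k`` SDs of baseline noise."""
    img = np.asarray(dff_image, dtype=float)
    return float(np.count_nonzero(img > k * baseline_noise_sd) * pixel_area_um2)
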