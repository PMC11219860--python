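"""Independent brute-force oracles used by the test suite."""

import numpy as np


def oracle_events(x, frame_interval, window_s=6.0, influence=0.2, k=5.0):
    """Literal, un-optimized re-implementation of the adaptive z-score recursion.

    Kept deliberately naive (python lists, per-step recomputation) so it
    stays independent of the vectorized implementation it checks.
    """
    lag = max(2, int(round(window_s / frame_interval)))
    filt = list(x[:lag])
    flags = [False] * len(x)
    prev_mean = np.mean(filt)
    prev_sd = np.std(filt, ddof=1)
    for t in range(lag, len(x)):
        if prev_sd > 0 and x[t] > prev_mean + k * prev_sd:
            flags[t] = True
            filt.append(influence * x[t] + (1 - influence) * filt[-1])
        else:
            filt.append(x[t])
        prev_mean = np.mean(filt[-lag:])
        prev_sd = np.std(filt[-lag:], ddof=1)

    fa = np.array(filt)
    roll_mean = np.full(len(x), np.nan)
    for t2 in range(lag - 1, len(x)):
        roll_mean[t2] = fa[t2 - lag + 1:t2 + 1].mean()

    events, t = [], lag
    while t < len(x):
        if flags[t]:
            start = t
            while t + 1 < len(x) and flags[t + 1]:
                t += 1
            seg = np.asarray(x[start:t + 1]) - roll_mean[start - 1]
            events.append((start * frame_interval,
                           (t - start + 1) * frame_interval, float(seg.max())))
        t += 1
    return events
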