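# Methods

This note records the models, conventions and numerical choices behind
`allolight`, and what the synthetic benchmarks do and do not establish.

## Allosteric dose-response model

Sensor titrations are modelled as four-parameter logistics evaluated in
log10 concentration, `R = bottom + (top − bottom)/(1 + 10^((log10 EC50 −
log10 c)·hill))`; zero-concentration points are evaluated directly at the
lower asymptote rather than through a log placeholder. The modulator acts
purely on apparent affinity (ternary-complex shift):

    EC50*(B) = EC50 (1 + B/Kb) / (1 + α B/Kb)

Efficacy modulation is deliberately out of scope: maximal responses are
unchanged by the modulator, so `top`, `bottom` and the Hill slope are
shared across the whole family and only the midpoint moves. The global
fit therefore has six free parameters regardless of family size.

**Fitting.** Bounded trust-region least squares (`scipy.optimize.
least_squares`) on (bottom, top, log10 EC50, hill, log10 Kb, log10 α),
with cost/step tolerances of 1e−14. Initialization is
data-driven: per-curve 4PL fits give the baseline EC50 (from the B = 0
curve), α from the maximal observed fold-shift, and Kb from the modulator
level whose fold-shift is closest to half-maximal, i.e. (1 + α)/2. On
solver failure up to three jittered restarts are drawn from a seeded
generator (default seed 0). Noiseless forward-model families refit to
better than 1e−6 relative; the identical-curves degenerate case converges
to α ≈ 1 with Kb unidentifiable (as it must be).

A small utility, `ec50_fold_change`, expresses the ratio of two apparent
affinities; it applies equally to molar EC50s, iontophoresis
ejection-current EC50s, and modulator Kb values across sensor variants.

## Single-fiber photometry

- **Preprocessing.** 2nd-order Butterworth low-pass applied
  forward-backward (zero phase), then decimation by block averaging. The
  cutoff is a per-experiment parameter (1–3 Hz typical); block averaging
  is used because the decimation method is otherwise unconstrained and it
  adds anti-aliasing for free.
- **Isosbestic ΔF/F0.** The ligand-insensitive 405 nm channel is
  regressed onto the 465 nm channel with a degree-1 least-squares fit over
  a configurable scope (whole recording, vehicle epoch, −60..+60 s around
  opto events, or −5..−1 s before behavioral events); the fitted reference
  is F0 and ΔF/F0 = (signal − F0)/F0 × 100. The result is invariant to a
  common gain on both channels. Scope windows are clipped to the
  recording; a window entirely outside it is an error.
- **Trials.** Segments are baseline-corrected by the mean over −10..−1 s;
  trials whose window leaves the recording are excluded and counted,
  never padded. Peak is the maximum and AUC the trapezoidal integral over
  the declared quantification window (0–10 s or 0–60 s).
- **Off-decay (mean lifetime).** A double exponential `A1 e^(−t/τ1) +
  A2 e^(−t/τ2)` with non-negative amplitudes and τ2 ≥ τ1 > 0 (no offset)
  is fitted from the peak (initialization τ1/τ2 at 10%/50% of the
  post-peak span); the reported time is the first 1/e crossing of the
  fitted curve, found by bisection. Non-convergence or no crossing within
  the trace yields NaN (the "undefined" flag). Single exponentials are
  recovered within 2% over τ ∈ [0.1, 20] s.
- **Stable imaging window.** Normalized peaks at 5/10/15/20 min post-drug
  define the plateau; trials in 5–65 min are scanned in order and the
  window is the maximal contiguous run from the first in-range trial with
  peaks inside plateau·(1 ± 0.15), closed interval (a peak at exactly 85%
  is included). One window per session; if the first trial is already
  outside tolerance the window is empty and flagged.
- **Long recordings.** Each channel is divided by its own degree-3
  polynomial fit (photobleaching); ΔF/F0 is the difference of the
  normalized channels. The tonic baseline is an 82 s moving median
  (windows specified in seconds and rounded to the nearest odd sample
  count), and its AUC is taken over +5..+40 min post-injection. Note the
  cubic fit absorbs part of any *persistent* step, so tonic effects are
  quantified as contrasts (post − pre, or drug − vehicle), which is also
  how the pipeline's recovery benchmark scores them.

## Imaging event detection

ROI traces (55 µm square tiles, edge remainders dropped) are screened
with an adaptive z-score rule: causal rolling mean and sample SD
(ddof = 1) over a 6 s trailing window are maintained on a *filtered* copy
of the trace; a frame is supra-threshold when the **raw** reading exceeds
mean + 5·SD, and flagged frames enter the filtered series with weight
0.2 (the influence factor), so large events only partially drag the
statistics upward. Consecutive supra-threshold frames merge into one
event (onset at the first frame, amplitude relative to the pre-event
rolling mean); one sub-threshold frame separates events. Influence 1
reduces to plain rolling statistics; influence 0 freezes them during an
event. The implementation is verified frame-for-frame against a literal
re-implementation of the recursion on hundreds of randomized traces.

Measured operating characteristics on white noise at the default 0.6 s
frame interval: ~4×10⁻⁴ spurious events per frame at k = 5, and ~86%
detection of isolated 8σ kernel-shaped events — the misses trace to the
10-frame SD estimate and to sub-threshold rise/decay frames inflating the
running statistics. Both figures are asserted (with margin) in the suite.

## Multi-fiber scales

Recordings are split at the injection; each segment gets an independent
2nd-order polynomial trend (local time origin for conditioning). The
post-injection trend carries the drug effect: its maximum (peak ΔFF0) and
the first crossing below peak/e (linearly interpolated between samples)
give the pharmacokinetic decay time; a trend that never crosses is
censored and the elapsed post-peak time reported as a lower bound.

Detrended residuals are decomposed with a continuous wavelet transform
(PyWavelets complex Morlet `cmor1.5-1.0`; family configurable) on 24
log-spaced pseudo-period scales from 1 to 30 s; scales longer than half
the epoch are masked. Epochs default to 30 min pre- and post-injection
with a 5 min post-injection blanking applied before extraction. Per-scale
mean coefficient magnitudes are compared channel-wise pre vs post with a
two-sided Wilcoxon signed-rank test (exact distribution below 25 pairs;
p = 1 by convention when all paired differences are zero), reported
unadjusted with a 0.05 mask plus an optional Bonferroni flag.

## Pharmacokinetics

Free brain concentration is total × unbound fraction. The shipped DETQ
profile holds the four printed anchors for a 10 mg/kg i.p. dose (270 nM
at 15 min, 110 nM at 45 min, 50 nM at 1 h, ≈0 at 2 h); intermediate
timepoints are user-supplied. Interpolation is log-linear between samples
(elimination is approximately first-order over this range), linear from
zero before the first sample, and exponential after the last using the
final two samples' log-slope; concentrations at or below 1 pM are clamped
to zero to avoid log-domain blowups. Occupancy is single-site
`B/(B + Kb)` and the effective sensor EC50*(t) is the composition of the
interpolated profile with the allosteric shift — bounded in
[EC50/α, EC50] and anti-monotone with the drug level.

## Synthetic data: what it emulates, and what it does not

All generators are bit-reproducible given (spec, seed) and record their
ground truth. The photometry session composes terms multiplicatively on
per-channel bleach envelopes:

    signal    = bleach465(t) · [1 + (tonic + transients + motion)/100] + ε
    reference = bleach405(t) · [1 + motion/100] + ε

so the motion artifact is shared, dopamine-dependent terms live only in
the signal channel, and the isosbestic correction is exactly solvable in
the noiseless limit. The tonic step follows receptor occupancy of the PK
profile scaled to its maximum; transients are difference-of-exponentials
kernels (defaults τ_r = 0.2 s, τ_d = 1.5 s, the order of magnitude of
dLight photometry transients). Default acquisition mirrors the
experimental designs: 1017.3 Hz sampling, trials every 5 min, the
0–450 nM modulator grid, 12-channel multi-fiber sessions with ~15 s
NAc-like, 10 s CPu-like and 3.5 s PFC-like tonic components.

The generators do **not** emulate hemodynamic or autofluorescence
contamination, nonstationary or non-Gaussian noise, imperfectly shared
motion between excitation channels, dopamine diffusion/reuptake kinetics,
or sensor nonlinearity near saturation. Passing recovery benchmarks
therefore establishes the correctness and calibration of the *analysis*
under the stated forward model, not performance bounds on arbitrary real
recordings.

## Benchmark problem sizes

The recovery studies are sized to be statistically meaningful while
keeping the full suite fast: the titration recovery uses 100 seeded
families (5% multiplicative noise, 8 modulator levels); the end-to-end
photometry benchmark uses twenty 26-minute two-channel sessions generated
at 203.46 Hz and downsampled 2× (the tonic step is scored at the
occupancy maximum of the moving-median baseline, the phasic amplitude as
the median trial peak); the scale-localization benchmark uses 8-channel
sessions at 4 Hz with 12-minute epochs. Median recovery errors are well
inside the ±10–15% acceptance bands (≈1% for the tonic step, ≈4% for
transient amplitude, ≤2% for α and Kb).

## Known limitations

- The stable-window algorithm assumes one contiguous plateau per session;
  sessions with transient dips below tolerance truncate the window early.
- The double-exponential off-decay has no offset term; traces with a
  non-zero asymptote bias the lifetime upward or fail to cross 1/e.
- The cubic bleach correction partially absorbs persistent tonic steps
  (quantify contrasts, not absolute levels).
- The adaptive detector's 10-frame statistics make single-frame events
  near threshold unreliable; its quantitative operating points above are
  specific to white noise.
- Wilcoxon scale comparisons treat channels as exchangeable paired units;
  channels within an animal are not independent, so p-values are
  descriptive (as used) rather than confirmatory across animals.
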