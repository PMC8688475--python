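# Methods

This note records the model choices, parameter semantics, and numerical
conventions behind fiberphot, and what its synthetic-data tests do and
do not establish.

## Signal model and normalization

A fiber-photometry session is modeled as two uniformly sampled channels:

```
control(t) = bleach_c(t) + artifact(t)            + noise
signal(t)  = bleach_s(t) + k·artifact(t) + act(t) + noise
```

where `bleach` is slow photobleaching, `artifact` is fast shared
contamination (motion, fiber bending), and `act` is indicator-dependent
activity present only in the signal channel. Because the artifact enters
both channels up to a scalar gain, an affine fit of the control onto the
signal (ordinary least squares, degree 1) yields a *fitted control* that
tracks both bleaching and artifacts; `ΔF/F = (signal − fitted)/fitted`
removes them and expresses activity as a fractional fluorescence change.

When no isosbestic channel exists, a pseudo-control is built by
smoothing the signal and fitting `a·exp(−t/τ) + c` with nonlinear least
squares (τ > 0 enforced; initialization `a = y₀ − y_end`, `c = y_end`,
`τ = duration/3`). A single exponential plus offset was chosen over a
double exponential as the minimal model that captures one dominant
bleaching time constant; if the optimizer fails to converge the code
falls back to a linear trend and logs a warning. The pseudo-control
corrects bleaching only — it cannot remove fast shared artifacts, and
the fit degrades when large transients dominate the smoothed trace.

## Channel alignment (harmonize)

Alternating-excitation systems sample the two channels on offset time
grids. Before the affine fit, the control is linearly interpolated onto
the signal channel's timestamps restricted to the channels' temporal
overlap; signal values are never modified. Signal frames up to half a
sample period beyond the control's range are retained, with the control
linearly extrapolated from its edge segment — this keeps the
first/last frames of a perfectly interleaved file instead of discarding
them, and is exact for locally affine controls. Linear interpolation
(error O(Δt²)) was preferred over spline or nearest-frame pairing as the
standard, artifact-free choice; it is this package's decision, not a
property inherited from any acquisition system.

## Zero-phase filtering

Denoising uses a uniform moving-average FIR kernel applied forward and
then backward. The forward–backward composition squares the magnitude
response and cancels the phase, so transients are not time-shifted —
verified in tests by brute-force cross-correlation of a symmetric pulse.
`filter_window` is the *per-pass* kernel length in samples (default
100, appropriate for kHz-class acquisition rates; at 20 Hz a window of
~5 samples ≈ 0.25 s is the comparable setting — the window must scale
with the sampling rate). Edges are reflect-padded by one window length
per pass and cropped, which avoids startup transients at light-on steps.
The filter is linear and preserves constants to 1e−12.

## Artifact excision and trimming

`trim_start` drops all samples and events before `t₀ + s` without
shifting the survivors. `apply_chunks` keeps only user-listed half-open
intervals `[start, end)`; both channels are cut at identical sample
indices, each kept chunk receives its own control fit (a single fit
spanning an excised artifact would be skewed by the discontinuity), and
ΔF/F chunks are concatenated before z-scoring. Retained event
timestamps are remapped to concatenated time by
`t' = chunk_offset + (t − chunk_start)`; because samples and events
shift by the same offsets, event-to-sample alignment is preserved
exactly (tested to 1e−12 on PSTHs before/after excising an untouched
interval). Events inside excised gaps are dropped and logged.

## z-scores

Three conventions, all on the concatenated ΔF/F trace:

- standard: `(x − mean(x)) / sd(x)`;
- baseline: mean and sd taken from a user window in absolute session
  seconds (half-open). The per-trial variant lives in the PSTH layer;
- modified: `0.6745·(x − median(x)) / MAD(x)` with the raw
  `MAD = median(|x − median|)` (no 1.4826 rescaling). 0.6745 is the
  0.75 normal quantile, making `0.6745/MAD` a consistent estimator of
  `1/σ` under Gaussian noise — locked by a 10⁵-draw regression test.

Standard deviations use the population convention (ddof = 0); the SEM
of PSTH/group averages uses the sample convention (ddof = 1) over √n.
Both conventions are locked by scalar-loop oracle tests. A constant
trace (sd or MAD zero) is a fatal error, as is a fitted control within
1e−9 of zero in the ΔF/F denominator.

## Transient detection

Two-stage robust thresholding on the z trace. Stage 1 partitions the
trace into consecutive non-overlapping windows (default 15 s; the last
partial window is processed as-is) and removes samples above
`median + 2·MAD` of their window; the survivors form the "resultant
trace". Stage 2 counts strict local maxima of the *full* trace above
`median + 3·MAD` of the resultant trace. Design choices: the window
steps disjointly rather than sliding per-sample (simplest reading,
locked by tests); removed samples leave the statistic pool only, since
deleting them from the trace would delete the transients being counted;
a plateau that rises then falls counts once at its first sample; peak
amplitude is the raw z value at the peak (no baseline subtraction); the
stage-2 threshold is `median + 3·MAD`, consistent with stage 1's
"above the median" form.

A consequence worth stating plainly: for Gaussian-tailed noise the
stage-2 threshold sits near 2σ, so a fixed, scale-invariant fraction of
noise local maxima always crosses it. Detection counts on noisy traces
therefore include supra-threshold noise peaks in addition to true
transients — hundreds per 30 min at 20 Hz — and the reported frequency
is `count/duration`, not an estimate of the true event rate. The tests
accordingly assert recall against injected ground truth (≥ 90% within
±0.25 s of the true peak times) and bound null-trace detections by
simulation, rather than asserting an absolute frequency.

## PSTH and measures

Trials are extracted on a uniform relative grid `[A, B)` with step
`1/rate` by nearest-sample lookup at `event + t` — events need not fall
on sample times, and nearest lookup avoids interpolation smearing.
Events whose window exceeds the recording are dropped and counted
(`n_trials + n_dropped == n_events`). Optional per-trial baseline
correction subtracts each trial's mean over a baseline window inside
`[A, B]`; corrected trials average exactly zero over that window. AUC
uses the trapezoidal rule (exact for affine traces, O(Δt²) otherwise);
the peak is the max of the mean PSTH in the window; at most 5 measure
windows. Per-trial AUC means equal the mean-PSTH AUC by linearity
(asserted to 1e−10); no such identity holds for peaks, so both
per-trial and mean-PSTH peaks are reported.

## Group averaging

Each session contributes exactly one trace — its mean PSTH — regardless
of trial count, so high-trial animals cannot dominate; trial-weighted
averaging was explicitly rejected. Grids and event names must match
exactly; mismatches are errors, never silent resampling. SEM across
sessions uses ddof = 1; a group of one reports SEM 0 with a warning.

## Synthetic sessions

The generator renders the signal model above: independent bleach
parameters per channel (defaults `0.3·e^(−t/600)+1.0` signal,
`0.2·e^(−t/400)+0.8` control, exercising the affine fit nontrivially),
Gaussian-bump artifacts injected identically (up to gain k) into both
channels, transients as difference-of-exponential kernels
`e^(−t/decay) − e^(−t/rise)` normalized to unit peak (rise 0.1 s, decay
1 s — the standard indicator shape, peaking 0.256 s after onset),
amplitude 5% ΔF/F, and 0.5% i.i.d. Gaussian sensor noise per channel.
Defaults describe a typical 10 min, 20 Hz striatal GCaMP session.
Output is bit-reproducible under a fixed seed.

Not emulated: hemodynamic contamination, indicator nonlinearity and
saturation, pink/drift noise, frame drops, or timestamp jitter. Green
tests on synthetic data therefore establish the correctness of the
arithmetic, alignment, and detection logic under the stated model — not
robustness to every pathology of real recordings.

## File formats

Channel CSVs: header `timestamps,data`, UTF-8, comma-separated, `.`
decimal. Event CSVs: single `timestamps` column; any such CSV in a
session folder is auto-attached as an event stream named by its file
stem. Interleaved camera CSVs: `FrameCounter,Timestamp,LedState,Region*`
(names configurable), partitioned by LED state then harmonized. CSVs
are parsed with round-trip float precision so write→read is
bit-identical. HDF5 output keys:
`/session/<id>/{dff,zscore,transients/...,psth/<event>/...,measures/<event>/...}`
with parameters recorded as attributes; 1-D/2-D arrays get CSV mirrors
(`%.17g`, also bit-exact). All internal times are float64 seconds; all
intervals are half-open `[start, end)`.
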