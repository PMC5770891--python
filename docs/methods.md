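# Methods

## The problem

Mobile brain/body imaging protocols record EEG and EMG (or other biosignals)
on separate devices, each free-running on its own crystal clock. The
manufacturer-advertised ("nominal") sampling rates are identical on paper —
typically 1000 Hz — but the true rates differ by parts per million, and the
recordings start at different instants. Over a ten-minute session a rate
mismatch of only 1.7 µHz relative already accumulates a millisecond of
misalignment; realistic hardware drifts of ~10⁻⁴ accumulate tens of
milliseconds within a minute, enough to corrupt brain–muscle connectivity
estimates that hinge on ~10–15 ms physiological delays.

When no shared trigger port, streaming API, or spare hardware channel is
available, a fallback is to inject an artificial fiducial pulse train into
both devices: the reference device annotates each pulse onset as a software
event, while the target device records the pulse as an analog deflection in
one of its channels. `spikesync` implements the offline half of that
strategy: detect the pulses in the analog trace, align the two streams, and
quantify how well synchronized they are.

## Alignment model

Both clocks are assumed affinely related over the session:

    t_ref = a + b · t_local,

with `b − 1` the relative clock drift (|b − 1| ≲ 10⁻³) and `a` the start
offset plus any fixed delivery/detection latency. Two fits are provided.

**PRE–POST (shift + linear time-warp).** Using the first `n_pre` and last
`n_post` paired pulses as anchors, the target stream is shifted so that the
*median* misalignment over the leading anchors is null, then linearly warped
(rescaled) so that the median over the trailing anchors is null as well.
Medians rather than means make single badly detected anchor pulses harmless.
Internally both conditions are imposed simultaneously: writing
`a(b) = median_PRE(r − b·t)`, the scale solves

    g(b) = median_POST(r − b·t) − median_PRE(r − b·t) = 0,

which is continuous, piecewise linear and strictly decreasing in `b`
(trailing pulse times exceed leading ones), hence has a unique root. The
two-median-anchor closed form provides the starting bracket; the root is
located by Brent's method and polished by identifying the median-attaining
elements and solving the local linear system exactly. Both anchor medians
are therefore zero to machine precision (< 10⁻¹² s), which the tests assert.

**PRE-only (shift only).** The offset is the median misalignment over the
first `n` pairs and the scale is pinned at 1 — this is what "trusting the
nominal sampling rate" means operationally. Any true drift δ then appears as
a residual trend of −δ ms per ms, which is exactly how the package estimates
drift from data.

Fitting happens entirely in the event domain; the analog trace is warped
once afterwards (`resample_trace`, linear interpolation at the pre-image
times, zero-padding or cropping outside the recorded span). This keeps
interpolation error out of the fit.

## Event pairing

Detected onsets are matched to reference events by a monotone greedy rule:
remove the coarse offset (difference of first elements), then match each
target event to the nearest still-available reference event within
`max_lag`, never crossing a previous match. For a train of period `P`,
`max_lag = P/2` (1 s by default) makes the matching unambiguous. A
brute-force dynamic program over all monotone matchings (maximize pairs,
then minimize total lag) serves as the oracle in the tests.

## Pulse detection

The analog pulse is shaped by the target device's hardware filters: with the
default morphology, a slow descent lasting 50 ms, a sharp drop to the
negative extreme, a rebound to the positive extreme, and an exponential
settle back below 1% of peak by 150 ms — about 200 ms of total occupancy,
which caps the usable pulse rate at 5 Hz (`max_pulse_rate`).

Onsets are detected as the first sample at which the deviation from baseline
(trace median; deviation absolute by default, since the waveform swings both
ways) crosses a threshold; subsequent crossings within a refractory window
(default 0.2 s, the waveform occupancy) are suppressed and counted.
Crossing times are at sample resolution by default; linear sub-sample
interpolation is available (`subsample=True`).

Two threshold strategies:

* **Noise percentile** — the configured percentile (default 99) of the
  deviation distribution of the pulse-free portions, found by a two-pass
  procedure: provisional detection at 50% of the global peak, excision of
  ±0.2 s around each provisional onset, percentile of the remainder. If the
  global peak is within ~10 robust standard deviations (1.4826·MAD) of the
  baseline the trace contains no pulse population (the maximum of pure
  Gaussian noise over any realistic trace length is ~5σ) and the percentile
  of the full trace is returned directly; if excision would remove ≥ 95% of
  samples the train is too dense for the trace length and an error is
  raised. Note that for an unbounded noise distribution any fixed percentile
  admits a fixed false-crossing rate, so this mode is best suited to real
  traces with bounded baseline activity.
* **Fraction of peak** — 5%, 10% or 20% (levels A/B/C) of the maximum
  detected peak amplitude, obtained from a permissive first pass. The
  simulated pipeline defaults to level A: lower thresholds cross earlier on
  the descent, where the crossing time is least sensitive to amplitude
  variation, so both the onset delay and its spread grow monotonically from
  A to C — the threshold-sweep ordering the tests check.

## Misalignment metrics

Residuals are evaluated on the *internal* pulses only (anchors excluded;
300 pulses with n = 10 at each end leave 280), in milliseconds, with the
sign convention `reference − mapped target` (positive = target lags).
`summarize_misalignment` reports the mean, the jitter (sample SD), the OLS
slope of residual on elapsed time (dimensionless, ms/ms) with its standard
error, the min/max range, and a Shapiro–Wilk Gaussianity verdict at
α = 0.05 (subsampled to at most 5000 points, seeded, since the test
degrades above that size). `compare_groups` runs one-way ANOVA across
residual sets from different anchor counts; its type-I error calibration is
verified by simulation.

Planning helpers invert the numbers: `time_to_misalignment(trend, bound)`
= bound/|trend|; `estimate_max_duration` additionally reserves `z·σ` of the
budget for jitter, `T_max = (bound − z·σ)/|trend|` with `z = 1.96` by
default — this coverage-factor formalization is this package's own choice
and is exposed as a parameter; `required_rate_precision(T, tol) = tol/T` is
the strict bound on |f₁ − f₂| (1.67 µHz for a 600 s session at a 1 ms
budget).

## Synthetic generator

`generate_recording` emulates the validation experiment: reference events at
k·period (default 2 s over 600 s → 300 pulses, optionally quantized to the
1 kHz grid, off by default since whether acquisition software rounds event
stamps is device-dependent); a target trace on a clock running at (1+δ)× the
reference rate from an offset start, with one waveform inserted per pulse at
the drifted plus i.i.d.-Gaussian-jittered local onset (evaluated at the
exact sub-sample offset), white Gaussian background noise (default
0.01 mV), and a slow ±20% single-cycle sinusoidal amplitude modulation
reproducing the observed variation of pulse amplitude across a session.
Timing and noise use independent seeded streams, so either can be held
fixed. Defaults mirror the experimental protocol: 2 s period, 4 ms / 3.2 mV
pulse, 600 s session, 1000 Hz; test sessions use δ = 10⁻⁴ and
σ_j = 1.7 ms as a realistic device regime.

What the generator does *not* contain: physiological signal (gait-locked
EMG bursts, cortical rhythms), movement or cable artifacts, line noise,
non-affine clock behaviour (temperature ramps), or amplitude-dependent
filter nonlinearity. Passing tests therefore demonstrate the estimators'
correctness under the stated model, not robustness to every artifact of
real recordings — which is why the percentile-threshold caveat above
matters in practice.

Two interactions discovered in validation are worth recording:

* The per-pulse jitter σ_j is not the only timing noise the pipeline sees:
  background noise perturbs the crossing time by σ_cross ≈ noise_sd /
  (descent slope), and the amplitude modulation moves the crossing point on
  the descent. The end-to-end jitter-recovery test disables amplitude
  modulation and checks the recovered SD against sqrt(σ_j² + σ_cross²)
  with σ_cross computed from the waveform geometry; the modulation effect
  is covered instead by the threshold-sweep ordering test, since it *is*
  the mechanism by which higher thresholds inflate jitter.
* Because the amplitude modulation completes one full cycle per session,
  its induced residual wobble integrates to a near-zero OLS slope at every
  threshold; the linear trend under PRE–POST alignment is therefore
  noise-level and not a monotone function of threshold, and no test claims
  it is.

## Numerical choices and degenerate inputs

* All internal times in seconds; reports in ms.
* Baseline = median of the full trace (robust to sparse pulses).
* `resample_trace` output grid aligned to `k/out_rate` in the reference
  clock; identity model at equal rates reproduces the input bit-for-bit.
* Empty event series pair to an empty pairing with a warning, not an error;
  an all-zero trace yields threshold 0 (degenerate); constant residuals
  skip Shapiro–Wilk with a degenerate flag; zero trend yields an unbounded
  (`inf`) duration sentinel.
* `estimate_max_duration` raises when `z·σ` already exhausts the bound.
* Anchor counts must satisfy `n_pre + n_post ≤` number of pairs and ≥ 3
  internal pulses must remain for statistics.

## Limitations

Pairwise streams only (no multi-stream merge), affine warps only (a
significant residual trend after PRE–POST alignment signals nonlinearity
the model cannot remove — the remedy is lower thresholds, shorter sessions,
or nonlinear warping, which is out of scope), no template-matching
detection, no online/streaming operation.
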