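# spikesync

Offline synchronization of independently clocked physiological recordings
via fiducial pulse trains.

## The problem

Multimodal recordings (EEG + EMG, and mobile brain/body imaging in general)
often come from separate devices whose clocks free-run: the advertised
sampling rates match on paper, but the true rates differ by parts per
million and the recordings start at different instants. Over a ten-minute
session a relative drift of 10⁻⁴ accumulates tens of milliseconds of
misalignment — fatal for analyses that depend on ~10–15 ms neuromuscular
conduction delays. When no shared trigger port or streaming API exists, a
practical fallback is to inject a known pulse train into both devices (a
digital trigger on one, an analog deflection on an electrode of the other)
and align the streams offline.

`spikesync` implements that offline alignment and its quality control:

* **detect** pulse onsets in the analog trace (noise-percentile or
  fraction-of-peak thresholds, refractory suppression);
* **align** the two streams — shift so the median misalignment of the first
  *n* pulses is null, then linearly time-warp so the median over the last
  *n* pulses is null (`t_ref = a + b·t_local`); a shift-only variant models
  "trust the nominal rate";
* **report** the residual misalignment on the internal pulses: jitter
  (standard deviation, σ), mean, linear trend (ms/ms), range, Shapiro–Wilk
  Gaussianity, plus one-way ANOVA across anchor counts;
* **plan** sessions with closed-form bounds: time to reach a misalignment
  budget (bound/|trend|), maximum session duration
  ((bound − z·σ)/|trend|), required rate agreement (|f₁−f₂| < tol/T), and
  the pulse-rate ceiling set by the filtered waveform's occupancy (1/0.2 s
  = 5 Hz);
* **simulate** complete two-device sessions with known clock drift δ,
  per-pulse jitter σ_j, background noise and the hardware-filtered spike
  waveform, for validation without hardware.

## Worked example

Simulate a 10-minute session — 300 pulses at 2 s intervals, 1000 Hz, a
relative clock drift of 10⁻⁴ and 1.7 ms per-pulse jitter — then detect,
align with 10 anchor pulses at each end, and report:

```
$ cat session.yaml
train:
  period: 2.0
  session_duration: 600.0
clock:
  drift: 1.0e-4
  jitter_sd: 1.7e-3

$ spikesync run --config session.yaml --seed 1
{
 "model": {
  "a": -0.010797698836789271,
  "b": 0.9998998358178406,
  "method": "prepost",
  "n_pre": 10,
  "n_post": 10
 },
 "detection": {
  "n_detected": 300,
  "threshold_mv": 0.19169765141376086,
  "n_rejected": 154
 },
 "metrics": {
  "mean_ms": 0.25441702265986016,
  "jitter_ms": 2.15775009733614,
  "trend_ms_per_ms": -7.342500378456183e-06,
  "trend_stderr_ms_per_ms": 6.668204219208567e-07,
  "range_ms": [-5.32437952648479, 6.01594787977433],
  "shapiro": {"stat": 0.994581712056076, "p": 0.4235027098723588, "gaussian": true},
  "n_internal": 280
 },
 "n_internal": 280
}
```

Reading the output: all 300 pulses were found at the 5%-of-peak threshold
(0.19 mV); the fitted warp `b = 0.99990…` is the inverse of the injected
drift (the target clock runs fast by 1.0×10⁻⁴, recovered to ~3×10⁻⁶); on
the 280 internal pulses the residual misalignment has σ ≈ 2.2 ms, a
[−5.3, 6.0] ms range, essentially no trend, and passes the Gaussianity
check — i.e. the two streams are synchronized to a few milliseconds over
the whole session. Running the same configuration with `--method pre_only`
instead leaves a trend of ≈ −1.1×10⁻⁴ ms/ms, reaching 10 ms of
desynchronization within ~90 s: nominal sampling rates alone cannot keep
two devices aligned, which is why the trailing anchors matter.

The same steps are available piecewise (`spikesync simulate / detect /
align / report / sweep`) on CSV event lists and traces, and as library
functions (`generate_recording`, `detect_spikes`, `fit_prepost_alignment`,
`summarize_misalignment`, …).

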