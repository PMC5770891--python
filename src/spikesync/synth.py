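"""Synthetic two-device recordings with known clock truth.

Emulates the validation setup: a pulse generator drives a digital trigger
input on the reference device (whose software annotates each onset as an
event) and an analog electrode on the target device, whose hardware filters
smear the 4 ms square pulse into a waveform spread over up to 200 ms — a slow
descent lasting ~50 ms, a sharp drop to the negative extreme, a rebound to the
positive extreme, and an exponential settle back to baseline within 150 ms.

The target device's clock runs at ``(1 + drift)`` times the reference rate and
starts with an offset; each recorded pulse onset additionally receives i.i.d.
Gaussian timing jitter.  Everything is reproducible from a single seed, with
independent timing and noise streams so one can be held fixed while the other
varies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timeline import EventSeries, PulseTrainSpec, SampledTrace

__all__ = [
    "ClockModel",
    "WaveformTemplate",
    "NoiseModel",
    "GroundTruth",
    "render_waveform",
    "waveform_value",
    "generate_recording",
    "PulseOverlapError",
]


class PulseOverlapError(ValueError):
    """Raised when the pulse period does not exceed the waveform occupancy."""


@dataclass(frozen=True)
class ClockModel:
    """Ground-truth relation between the target and reference clocks.

    ``offset`` is the target clock's start minus the reference clock's start
    (s); the target clock advances at ``(1 + drift)`` times the reference
    rate, so a reference instant ``t`` reads ``(1 + drift) * (t - offset)`` on
    the target clock.  ``jitter_sd`` is the standard deviation (s) of i.i.d.
    Gaussian noise on each recorded pulse onset.
    """

    offset: float = 0.0
    drift: float = 0.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if 1.0 + self.drift <= 0:
            raise ValueError("1 + drift must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    def to_target(self, t_reference: np.ndarray) -> np.ndarray:
        return (1.0 + self.drift) * (np.asarray(t_reference, float) - self.offset)


@dataclass(frozen=True)
class WaveformTemplate:
    """Shape of one hardware-filtered pulse, normalized to unit peak.

    Piecewise: zero baseline, linear descent over ``descent_duration`` to a
    shoulder, sharp drop to ``trough_level`` (-1), linear rebound to
    ``rebound_level`` (+1), then exponential settle with time constant
    ``settle_tau`` — below 1% of peak by 0.15 s with the defaults — and exactly
    zero from ``occupancy`` onwards.  ``peak_mv`` scales to millivolts and
    ``amplitude_drift`` applies a slow sinusoidal modulation (one cycle over
    the session, ±20% by default) reproducing the observed variation of pulse
    amplitude across a recording.

    ``kind='highpass_square'`` substitutes the analytic response of a
    first-order high-pass filter to the raw square pulse, for sensitivity
    checks against the piecewise morphology.
    """

    descent_duration: float = 0.05
    shoulder_level: float = -0.3
    drop_duration: float = 0.002
    trough_level: float = -1.0
    rebound_duration: float = 0.005
    rebound_level: float = 1.0
    settle_tau: float = 0.018
    occupancy: float = 0.2
    peak_mv: float = 3.2
    amplitude_drift: float = 0.2
    drift_cycles: float = 1.0
    kind: str = "piecewise"
    highpass_tau: float = 0.02

    def __post_init__(self) -> None:
        if self.occupancy <= 0 or self.peak_mv <= 0:
            raise ValueError("occupancy and peak_mv must be > 0")
        if not (self.trough_level < 0 < self.rebound_level):
            raise ValueError("trough and rebound levels must bracket baseline")
        if self.descent_duration < 0:
            raise ValueError("descent_duration must be >= 0")
        if self.kind not in ("piecewise", "highpass_square"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Additive white Gaussian background noise (mV)."""

    sd: float = 0.01

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows, for parameter-recovery tests."""

    pulse_times_reference: np.ndarray
    pulse_times_target_clock: np.ndarray
    offset: float
    drift: float
    jitter_draws: np.ndarray
    amplitude_factors: np.ndarray
    seed: int


def waveform_value(
    template: WaveformTemplate, t: np.ndarray, pulse_width: float = 0.004
) -> np.ndarray:
    """Normalized waveform amplitude at times ``t`` (s) after pulse onset."""
    t = np.asarray(t, float)
    if template.kind == "highpass_square":
        tau = template.highpass_tau
        y = np.where(
            (t >= 0) & (t < template.occupancy),
            np.exp(-np.maximum(t, 0) / tau)
            - np.where(t >= pulse_width, np.exp(-np.maximum(t - pulse_width, 0) / tau), 0.0),
            0.0,
        )
        peak = np.abs(y).max(initial=0.0)
        return y / peak if peak > 0 else y

    t1 = template.descent_duration
    # no descent means an immediate drop: the waveform starts at the trough
    t2 = t1 + (template.drop_duration if t1 > 0 else 0.0)
    t3 = t2 + template.rebound_duration
    conds = [
        (t < 0) | (t >= template.occupancy),
        t < t1,
        t < t2,
        t < t3,
    ]
    with np.errstate(invalid="ignore", divide="ignore"):
        choices = [
            np.zeros_like(t),
            template.shoulder_level * np.where(t1 > 0, t / max(t1, 1e-300), 0.0),
            template.shoulder_level
            + (template.trough_level - template.shoulder_level)
            * (t - t1) / max(t2 - t1, 1e-300),
            template.trough_level
            + (template.rebound_level - template.trough_level)
            * (t - t2) / max(t3 - t2, 1e-300),
        ]
    settle = template.rebound_level * np.exp(-(t - t3) / template.settle_tau)
    return np.select(conds, choices, default=settle)


def render_waveform(template: WaveformTemplate, rate: float) -> np.ndarray:
    """Sample the unit-peak waveform on a uniform grid at ``rate`` Hz."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    n = int(round(template.occupancy * rate))
    if n < 4:
        raise ValueError(
            f"waveform occupancy {template.occupancy}s at {rate} Hz yields only {n} samples"
        )
    return waveform_value(template, np.arange(n) / rate)


def generate_recording(
    train: PulseTrainSpec | None = None,
    clock: ClockModel | None = None,
    wave: WaveformTemplate | None = None,
    noise: NoiseModel | None = None,
    rate: float = 1000.0,
    quantize_reference: bool = False,
) -> tuple[EventSeries, SampledTrace, GroundTruth]:
    """Generate a paired (reference event series, target analog trace) session.

    Reference events fall at ``k * period`` for ``k = 0 .. n_pulses - 1``,
    optionally quantized to the reference sampling grid (whether the reference
    software rounds event timestamps to its own grid is device-dependent, so it
    is exposed as an option).  The target trace lives on the target clock: one
    waveform per pulse is inserted at the drifted and jittered local onset by
    evaluating the template at the exact sub-sample offset, scaled by the
    slowly modulated amplitude, with white noise added throughout.
    """
    train = train or PulseTrainSpec()
    clock = clock or ClockModel()
    wave = wave or WaveformTemplate()
    noise = noise if noise is not None else NoiseModel()
    if train.period <= wave.occupancy:
        raise PulseOverlapError(
            f"pulse period {train.period}s must exceed waveform occupancy "
            f"{wave.occupancy}s (max usable pulse rate is {1 / wave.occupancy:g} Hz)"
        )

    timing_rng, noise_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(clock.seed).spawn(2)
    )

    n_pulses = train.n_pulses
    t_ref = np.arange(n_pulses) * train.period
    if quantize_reference:
        t_ref = np.round(t_ref * rate) / rate
    jitter = (
        timing_rng.normal(0.0, clock.jitter_sd, n_pulses)
        if clock.jitter_sd > 0
        else np.zeros(n_pulses)
    )
    t_local = clock.to_target(np.arange(n_pulses) * train.period) + jitter

    end_local = clock.to_target(train.session_duration)
    n_samples = int(np.ceil(end_local * rate))
    values = (
        noise_rng.normal(0.0, noise.sd, n_samples) if noise.sd > 0 else np.zeros(n_samples)
    )

    amp = 1.0 + wave.amplitude_drift * np.sin(
        2.0 * np.pi * wave.drift_cycles * t_ref / train.session_duration
    )
    occ_samples = int(np.ceil(wave.occupancy * rate)) + 1
    for t0, a in zip(t_local, amp):
        i0 = max(0, int(np.ceil(t0 * rate)))
        i1 = min(n_samples, i0 + occ_samples)
        if i1 <= i0:
            continue
        grid = np.arange(i0, i1) / rate
        values[i0:i1] += wave.peak_mv * a * waveform_value(
            wave, grid - t0, pulse_width=train.pulse_width
        )

    events = EventSeries(t_ref, clock_label="reference")
    trace = SampledTrace(values, rate_nominal=rate, start_time=0.0, label="target")
    truth = GroundTruth(
        pulse_times_reference=t_ref,
        pulse_times_target_clock=t_local,
        offset=clock.offset,
        drift=clock.drift,
        jitter_draws=jitter,
        amplitude_factors=amp,
        seed=clock.seed,
    )
    return events, trace, truth
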