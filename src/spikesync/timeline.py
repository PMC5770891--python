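"""Core time-base types and alignment fitting.

All times are kept in seconds internally; reports convert to milliseconds at
the boundary.  The misalignment sign convention throughout the package is

    misalignment = reference time - mapped target time

so a positive value means the target stream lags the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SampledTrace",
    "EventSeries",
    "PulseTrainSpec",
    "AlignmentModel",
    "EventPairing",
    "pair_events",
    "fit_prepost_alignment",
    "fit_pre_alignment",
    "transform_events",
    "resample_trace",
    "InsufficientAnchorsError",
    "DegenerateSpanError",
]


class InsufficientAnchorsError(ValueError):
    """Raised when fewer pulse pairs are available than anchors requested."""


class DegenerateSpanError(ValueError):
    """Raised when the leading and trailing anchor epochs coincide in time."""


@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled analog channel in its device's local clock.

    Sample ``k`` sits at time ``start_time + k / rate_nominal``.  The nominal
    rate is the manufacturer-advertised one; the device's true rate may differ
    by a few parts per million, which is precisely what alignment corrects.
    """

    values: np.ndarray
    rate_nominal: float
    start_time: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.rate_nominal <= 0:
            raise ValueError(f"rate_nominal must be > 0, got {self.rate_nominal}")
        if values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if values.size and not np.all(np.isfinite(values)):
            raise ValueError("trace amplitudes must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in the trace's local clock (s)."""
        return self.start_time + np.arange(self.values.size) / self.rate_nominal

    @property
    def duration(self) -> float:
        return self.values.size / self.rate_nominal


@dataclass(frozen=True)
class EventSeries:
    """Strictly increasing pulse-onset times (s) in a single clock."""

    times: np.ndarray
    clock_label: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.size and not np.all(np.isfinite(times)):
            raise ValueError("event times must be finite")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise ValueError(f"event times must be strictly increasing (violation at index {bad})")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class PulseTrainSpec:
    """Protocol of the delivered synchronization pulse train.

    Defaults describe a 10-minute session with one 4 ms, 3.2 mV pulse every
    2 s, i.e. 300 pulses total.
    """

    period: float = 2.0
    pulse_width: float = 0.004
    pulse_amplitude: float = 3.2
    session_duration: float = 600.0

    def __post_init__(self) -> None:
        if self.period <= 0 or self.pulse_width <= 0 or self.session_duration <= 0:
            raise ValueError("period, pulse_width and session_duration must be > 0")

    @property
    def n_pulses(self) -> int:
        return int(np.floor(self.session_duration / self.period))


@dataclass(frozen=True)
class AlignmentModel:
    """Affine map from a local clock to the reference clock.

    ``t_ref = offset + scale * t_local``.  ``method`` records whether the model
    was fitted from leading and trailing anchors (``prepost``) or leading
    anchors only (``pre_only``, in which case ``scale`` is exactly 1 and the
    nominal sampling rate is trusted).
    """

    offset: float
    scale: float = 1.0
    n_pre: int = 0
    n_post: int = 0
    method: str = "prepost"

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.method not in ("prepost", "pre_only", "identity"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "pre_only" and (self.scale != 1.0 or self.n_post != 0):
            raise ValueError("pre_only alignment requires scale == 1 and n_post == 0")

    def apply(self, times: np.ndarray) -> np.ndarray:
        return self.offset + self.scale * np.asarray(times, dtype=float)

    def invert(self) -> "AlignmentModel":
        return AlignmentModel(
            offset=-self.offset / self.scale,
            scale=1.0 / self.scale,
            n_pre=self.n_pre,
            n_post=self.n_post,
            method="identity",
        )

    @staticmethod
    def identity() -> "AlignmentModel":
        return AlignmentModel(offset=0.0, scale=1.0, method="identity")


@dataclass(frozen=True)
class EventPairing:
    """Monotone one-to-one matching between reference and target events."""

    reference_indices: np.ndarray
    target_indices: np.ndarray
    max_lag: float
    n_unmatched_reference: int = 0
    n_unmatched_target: int = 0

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_indices, dtype=int)
        tgt = np.asarray(self.target_indices, dtype=int)
        object.__setattr__(self, "reference_indices", ref)
        object.__setattr__(self, "target_indices", tgt)
        if ref.size != tgt.size:
            raise ValueError("pairing index arrays must have equal length")
        for name, idx in (("reference", ref), ("target", tgt)):
            if idx.size > 1 and not np.all(np.diff(idx) > 0):
                raise ValueError(f"{name} indices must be strictly increasing")

    def __len__(self) -> int:
        return self.reference_indices.size

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.reference_indices.tolist(), self.target_indices.tolist()))


def pair_events(reference: EventSeries, target: EventSeries, max_lag: float) -> EventPairing:
    """Match target events to reference events one-to-one, preserving order.

    The coarse clock offset (difference of the first elements) is removed, then
    each target event is matched to the nearest not-yet-matched reference event
    whose index exceeds the previously matched one, provided the residual lag is
    within ``max_lag``.  Events that cannot be matched are dropped and counted.

    For a pulse train of period ``P`` a ``max_lag`` of ``P / 2`` guarantees an
    unambiguous matching.
    """
    if max_lag <= 0:
        raise ValueError(f"max_lag must be > 0, got {max_lag}")
    ref = reference.times
    tgt = target.times
    if ref.size == 0 or tgt.size == 0:
        warnings.warn("pairing an empty event series yields an empty pairing", stacklevel=2)
        return EventPairing(
            np.empty(0, int), np.empty(0, int), max_lag,
            n_unmatched_reference=ref.size, n_unmatched_target=tgt.size,
        )

    coarse = tgt[0] - ref[0]
    shifted = tgt - coarse

    ref_pairs: list[int] = []
    tgt_pairs: list[int] = []
    next_ref = 0  # smallest reference index still available
    for j, t in enumerate(shifted):
        if next_ref >= ref.size:
            break
        # nearest available reference event, respecting monotonicity
        k = int(np.searchsorted(ref, t, side="left"))
        k = max(k, next_ref)
        best = None
        for cand in (k - 1, k):
            if cand < next_ref or cand >= ref.size:
                continue
            lag = abs(ref[cand] - t)
            if lag <= max_lag and (best is None or lag < abs(ref[best] - t)):
                best = cand
        if best is not None:
            ref_pairs.append(best)
            tgt_pairs.append(j)
            next_ref = best + 1

    return EventPairing(
        np.asarray(ref_pairs, int),
        np.asarray(tgt_pairs, int),
        max_lag,
        n_unmatched_reference=ref.size - len(ref_pairs),
        n_unmatched_target=tgt.size - len(tgt_pairs),
    )


def _paired_times(
    reference: EventSeries, target: EventSeries, pairing: EventPairing
) -> tuple[np.ndarray, np.ndarray]:
    return (
        reference.times[pairing.reference_indices],
        target.times[pairing.target_indices],
    )


def fit_prepost_alignment(
    reference: EventSeries,
    target: EventSeries,
    pairing: EventPairing,
    n_pre: int,
    n_post: int,
) -> AlignmentModel:
    """Fit shift + linear time-warp from leading and trailing anchor pulses.

    The target stream is first shifted so the median misalignment over the
    first ``n_pre`` pairs is null, then linearly warped so the median over the
    last ``n_post`` pairs is null as well.  Both anchor medians are driven to
    zero simultaneously: with ``a(b) = median_PRE(r - b t)`` the scale ``b``
    solves ``median_POST(r - b t) = a(b)``, a strictly decreasing piecewise
    linear equation with a unique root.  The root is bracketed from the
    two-median-anchor closed form and polished by identifying the median
    elements and solving the local linear system, so the anchor medians are
    zero to machine precision.
    """
    if n_pre < 1 or n_post < 1:
        raise ValueError("n_pre and n_post must each be >= 1")
    if n_pre + n_post > len(pairing):
        raise InsufficientAnchorsError(
            f"need n_pre + n_post = {n_pre + n_post} pairs, have {len(pairing)}"
        )
    r, t = _paired_times(reference, target, pairing)
    r_pre, t_pre = r[:n_pre], t[:n_pre]
    r_post, t_post = r[-n_post:], t[-n_post:]

    anchor_pre = float(np.median(r_pre))
    anchor_post = float(np.median(r_post))
    if anchor_post <= anchor_pre:
        raise DegenerateSpanError("leading and trailing anchor epochs coincide")

    def gap(b: float) -> float:
        # POST median misalignment after shifting PRE median to zero
        a = np.median(r_pre - b * t_pre)
        return float(np.median(r_post - b * t_post) - a)

    # closed-form initial guess through the two median anchor points
    d_pre = float(np.median(r_pre - t_pre))
    d_post = float(np.median(r_post - t_post))
    b0 = (anchor_post - anchor_pre) / ((anchor_post - d_post) - (anchor_pre - d_pre))
    if b0 <= 0:
        b0 = 1.0

    g0 = gap(b0)
    if g0 == 0.0:
        b = b0
    else:
        # bracket the root; gap is strictly decreasing in b
        step = max(abs(b0) * 1e-6, 1e-9)
        lo, hi = b0, b0
        while gap(lo) < 0:
            lo -= step
            step *= 4
        step = max(abs(b0) * 1e-6, 1e-9)
        while gap(hi) > 0:
            hi += step
            step *= 4
        b = brentq(gap, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200) if lo < hi else lo

    # polish: at the root the median is attained by fixed elements (or the mean
    # of the two middle ones); solve the resulting linear system exactly.
    for _ in range(3):
        alpha_pre, beta_pre = _median_anchor(r_pre, t_pre, b)
        alpha_post, beta_post = _median_anchor(r_post, t_post, b)
        denom = beta_post - beta_pre
        if denom == 0:
            break
        b_new = (alpha_post - alpha_pre) / denom
        if b_new <= 0 or not np.isfinite(b_new):
            break
        if b_new == b:
            break
        b = b_new
    a = float(np.median(r_pre - b * t_pre))
    return AlignmentModel(offset=a, scale=float(b), n_pre=n_pre, n_post=n_post, method="prepost")


def _median_anchor(r: np.ndarray, t: np.ndarray, b: float) -> tuple[float, float]:
    """Median of ``r - b*t`` written as ``alpha - beta*b`` for the local ordering."""
    resid = r - b * t
    order = np.argsort(resid, kind="stable")
    n = resid.size
    if n % 2:
        sel = order[n // 2 : n // 2 + 1]
    else:
        sel = order[n // 2 - 1 : n // 2 + 1]
    return float(np.mean(r[sel])), float(np.mean(t[sel]))


def fit_pre_alignment(
    reference: EventSeries,
    target: EventSeries,
    pairing: EventPairing,
    n: int,
) -> AlignmentModel:
    """Shift-only alignment from the first ``n`` pairs (nominal rate trusted).

    The offset is the median misalignment over the leading pairs; the scale is
    exactly 1, so any true rate discrepancy shows up as a linear residual trend.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > len(pairing):
        raise InsufficientAnchorsError(f"need {n} pairs, have {len(pairing)}")
    r, t = _paired_times(reference, target, pairing)
    a = float(np.median(r[:n] - t[:n]))
    return AlignmentModel(offset=a, scale=1.0, n_pre=n, n_post=0, method="pre_only")


def transform_events(events: EventSeries, model: AlignmentModel) -> EventSeries:
    """Map event times into the reference clock (order is preserved)."""
    return EventSeries(model.apply(events.times), clock_label=events.clock_label)


def resample_trace(
    trace: SampledTrace,
    model: AlignmentModel,
    out_rate: float | None = None,
    edge: str = "pad",
) -> SampledTrace:
    """Linearly resample a trace onto a uniform grid in the reference clock.

    Output samples sit on the grid ``k / out_rate`` of the reference clock,
    spanning the trace's nominal window.  Each output amplitude is the linear
    interpolation of the input at the pre-image time ``(t_out - a) / b``.
    Reference times whose pre-image falls before the first or after the last
    input sample are zero-padded (``edge='pad'``) or dropped (``edge='crop'``).
    """
    if out_rate is None:
        out_rate = trace.rate_nominal
    if out_rate <= 0:
        raise ValueError("out_rate must be > 0")
    if edge not in ("pad", "crop"):
        raise ValueError("edge must be 'pad' or 'crop'")
    n = trace.values.size
    if n == 0:
        return replace(trace, values=np.empty(0), rate_nominal=out_rate)

    eps = 1e-9 / out_rate
    k0 = int(np.ceil(trace.start_time * out_rate - eps))
    k1 = int(np.floor((trace.start_time + (n - 1) / trace.rate_nominal) * out_rate + eps))
    if k1 < k0:
        return replace(trace, values=np.empty(0), rate_nominal=out_rate, start_time=k0 / out_rate)
    t_out = (k0 + np.arange(k1 - k0 + 1)) / out_rate
    pre_image = (t_out - model.offset) / model.scale
    t_in = trace.start_time + np.arange(n) / trace.rate_nominal
    values = np.interp(pre_image, t_in, trace.values, left=0.0, right=0.0)
    start = k0 / out_rate
    if edge == "crop":
        inside = (pre_image >= t_in[0]) & (pre_image <= t_in[-1])
        if not inside.any():
            return replace(trace, values=np.empty(0), rate_nominal=out_rate, start_time=start)
        first, last = np.flatnonzero(inside)[[0, -1]]
        values = values[first : last + 1]
        start = (k0 + first) / out_rate
    return SampledTrace(values, rate_nominal=out_rate, start_time=start, label=trace.label)
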