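"""Residual misalignment statistics and session-planning bounds.

After alignment, the pulses that served as anchors are exact by construction,
so synchronization quality is judged on the internal ("middle") pulses only:
their residual misalignment distribution gives the jitter (standard
deviation), a linear trend over time (evidence of uncorrected or nonlinear
clock behaviour), the range, and a Gaussianity verdict.

The planning helpers invert those numbers: how long can a session run before
the misalignment budget is exhausted, how precisely matched must two nominal
sampling rates be, and how fast can pulses be delivered given the waveform
occupancy imposed by hardware filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .timeline import AlignmentModel, EventPairing, EventSeries

__all__ = [
    "StatConfig",
    "MisalignmentReport",
    "RateBudget",
    "misalignment_series",
    "summarize_misalignment",
    "compare_groups",
    "estimate_max_duration",
    "time_to_misalignment",
    "required_rate_precision",
    "max_pulse_rate",
    "InsufficientDataError",
    "InfeasibleBudgetError",
]

UNBOUNDED = math.inf


class InsufficientDataError(ValueError):
    """Raised when fewer than three internal pulses are available."""


class InfeasibleBudgetError(ValueError):
    """Raised when the misalignment budget is already consumed by jitter."""


@dataclass(frozen=True)
class StatConfig:
    """Statistical-testing parameters.

    Shapiro-Wilk is unreliable above a few thousand points, so samples larger
    than ``max_test_n`` are subsampled without replacement (seeded).
    """

    alpha: float = 0.05
    max_test_n: int = 5000
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_test_n < 3:
            raise ValueError("max_test_n must be >= 3")


@dataclass(frozen=True)
class MisalignmentReport:
    """Summary of the internal-pulse residual distribution (ms)."""

    residuals: np.ndarray
    times: np.ndarray
    mean: float
    jitter_sd: float
    trend: float
    trend_stderr: float
    range: tuple[float, float]
    shapiro_stat: float | None
    shapiro_p: float | None
    is_gaussian: bool | None
    n_internal: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_ms": self.mean,
            "jitter_ms": self.jitter_sd,
            "trend_ms_per_ms": self.trend,
            "trend_stderr_ms_per_ms": self.trend_stderr,
            "range_ms": [self.range[0], self.range[1]],
            "shapiro": {
                "stat": self.shapiro_stat,
                "p": self.shapiro_p,
                "gaussian": self.is_gaussian,
            },
            "n_internal": self.n_internal,
        }


@dataclass(frozen=True)
class RateBudget:
    """Sampling-rate agreement needed to hold misalignment below ``tol``.

    Two free-running devices at true rates ``f1`` and ``f2`` accumulate
    ``|f1 - f2| * T`` sample periods of misalignment over a recording of
    duration ``T``; keeping that below ``tol`` requires
    ``|f1 - f2| < tol / T``.
    """

    f1: float
    f2: float
    T: float
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.T <= 0 or self.tol <= 0:
            raise ValueError("T and tol must be > 0")

    @property
    def delta_f_bound(self) -> float:
        return self.tol / self.T

    @property
    def satisfied(self) -> bool:
        return abs(self.f1 - self.f2) * self.T < self.tol


def misalignment_series(
    reference: EventSeries,
    mapped_target: EventSeries,
    pairing: EventPairing,
    model: AlignmentModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pulse residuals (ms) on the internal pulses.

    ``mapped_target`` must already be in the reference clock.  The leading
    ``n_pre`` and trailing ``n_post`` anchor pairs are excluded: they are zero
    (in median) by construction and would bias the statistics.  Times are taken
    from the reference clock (s).
    """
    r = reference.times[pairing.reference_indices]
    t = mapped_target.times[pairing.target_indices]
    lo = model.n_pre
    hi = len(pairing) - model.n_post
    if hi - lo < 3:
        raise InsufficientDataError(
            f"only {max(hi - lo, 0)} internal pulses after removing anchors; need >= 3"
        )
    residuals_ms = (r[lo:hi] - t[lo:hi]) * 1e3
    return r[lo:hi], residuals_ms


def summarize_misalignment(
    times: np.ndarray, residuals: np.ndarray, stat: StatConfig | None = None
) -> MisalignmentReport:
    """Mean, jitter (sample SD), OLS trend, range and Shapiro-Wilk verdict.

    The trend is the ordinary-least-squares slope of residual (ms) on elapsed
    time (ms), hence dimensionless and reported in ms per ms.
    """
    stat = stat or StatConfig()
    times = np.asarray(times, float)
    residuals = np.asarray(residuals, float)
    if residuals.size < 3:
        raise InsufficientDataError("need >= 3 residuals")
    if times.shape != residuals.shape:
        raise ValueError("times and residuals must have equal length")

    mean = float(np.mean(residuals))
    sd = float(np.std(residuals, ddof=1))
    elapsed_ms = (times - times[0]) * 1e3
    if np.ptp(elapsed_ms) == 0:
        raise ValueError("residual times must span a nonzero interval")
    fit = stats.linregress(elapsed_ms, residuals)
    rng_lo, rng_hi = float(np.min(residuals)), float(np.max(residuals))

    degenerate = np.ptp(residuals) == 0
    if degenerate:
        shapiro_stat = shapiro_p = is_gaussian = None
    else:
        sample = residuals
        if sample.size > stat.max_test_n:
            rng = np.random.default_rng(stat.subsample_seed)
            sample = rng.choice(sample, size=stat.max_test_n, replace=False)
        sw = stats.shapiro(sample)
        shapiro_stat, shapiro_p = float(sw.statistic), float(sw.pvalue)
        is_gaussian = bool(shapiro_p >= stat.alpha)

    return MisalignmentReport(
        residuals=residuals,
        times=times,
        mean=mean,
        jitter_sd=sd,
        trend=float(fit.slope),
        trend_stderr=float(fit.stderr),
        range=(rng_lo, rng_hi),
        shapiro_stat=shapiro_stat,
        shapiro_p=shapiro_p,
        is_gaussian=is_gaussian,
        n_internal=residuals.size,
        degenerate=bool(degenerate),
    )


def compare_groups(
    groups: list[np.ndarray], stat: StatConfig | None = None
) -> tuple[float, float, bool]:
    """One-way ANOVA across residual groups; returns (F, p, reject)."""
    stat = stat or StatConfig()
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp([a[0] for a in arrays]) == 0:
        return math.nan, math.nan, False  # identical constant groups: degenerate
    f_stat, p = stats.f_oneway(*arrays)
    return float(f_stat), float(p), bool(p < stat.alpha)


def estimate_max_duration(
    trend: float, jitter_sd: float, bound: float, z: float = 1.96
) -> float:
    """Longest recording (s) keeping |misalignment| within ``bound`` ms.

    Treats the residual as a linear drift at ``trend`` (ms/ms) plus Gaussian
    jitter; the budget left for drift after reserving ``z`` standard deviations
    for jitter is ``bound - z * jitter_sd``, so
    ``T_max = (bound - z * jitter_sd) / |trend|`` (converted to seconds).  The
    coverage factor is this package's formalization; with ``z = 1.96`` roughly
    97.5% of pulses stay within the bound at the end of the session.
    """
    if jitter_sd < 0 or bound <= 0:
        raise ValueError("jitter_sd must be >= 0 and bound > 0")
    budget = bound - z * jitter_sd
    if budget <= 0:
        raise InfeasibleBudgetError(
            f"bound {bound} ms <= z * jitter {z * jitter_sd:.3g} ms: no drift budget left"
        )
    if trend == 0:
        return UNBOUNDED
    return budget / abs(trend) / 1e3


def time_to_misalignment(trend: float, bound: float) -> float:
    """Time (s) for a linear drift of ``trend`` ms/ms to accumulate ``bound`` ms."""
    if bound <= 0:
        raise ValueError("bound must be > 0")
    if trend == 0:
        return UNBOUNDED
    return bound / abs(trend) / 1e3


def required_rate_precision(T: float, tol: float = 1e-3) -> float:
    """Strict upper bound (Hz) on |f1 - f2| so misalignment stays below ``tol``.

    Equality ``bound * T = tol`` holds exactly; e.g. a 600 s session with a
    1 ms budget demands the two rates agree to better than 1.67e-6 Hz, far
    beyond any advertised nominal-rate precision.
    """
    if T <= 0 or tol <= 0:
        raise ValueError("T and tol must be > 0")
    return tol / T


def max_pulse_rate(waveform_occupancy: float) -> float:
    """Fastest pulse delivery (Hz) such that consecutive waveforms cannot overlap.

    With hardware filters spreading each pulse over 200 ms this caps the train
    at 5 Hz.
    """
    if waveform_occupancy <= 0:
        raise ValueError("waveform_occupancy must be > 0")
    return 1.0 / waveform_occupancy
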