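"""Shared fixtures: a realistic synthetic session and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from spikesync import (
    ClockModel,
    EventSeries,
    NoiseModel,
    PulseTrainSpec,
    WaveformTemplate,
    generate_recording,
)

# Realistic device regime for end-to-end tests: a relative clock drift of
# 1e-4 (about what free-running consumer amplifiers exhibit over minutes) and
# 1.7 ms per-pulse timing jitter.
SESSION_DRIFT = 1e-4
SESSION_JITTER = 1.7e-3
SESSION_SEED = 7


@pytest.fixture(scope="session")
def default_session():
    """Full 10-min, 1000 Hz, 300-pulse session with drift and jitter."""
    events, trace, truth = generate_recording(
        PulseTrainSpec(),
        ClockModel(drift=SESSION_DRIFT, jitter_sd=SESSION_JITTER, seed=SESSION_SEED),
        WaveformTemplate(),
        NoiseModel(),
    )
    return events, trace, truth


@pytest.fixture(scope="session")
def short_session():
    """60 s session (30 pulses) for quicker end-to-end checks."""
    events, trace, truth = generate_recording(
        PulseTrainSpec(session_duration=60.0),
        ClockModel(drift=SESSION_DRIFT, jitter_sd=SESSION_JITTER, seed=SESSION_SEED),
        WaveformTemplate(),
        NoiseModel(),
    )
    return events, trace, truth


def brute_force_pairing(reference: np.ndarray, target: np.ndarray, max_lag: float):
    """All monotone matchings; maximize pair count, then minimize total |lag|.

    Lags are computed after removing the coarse offset (difference of the
    first elements).  Exponential enumeration — use only on tiny series.
    """
    shifted = target - (target[0] - reference[0])
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best_suffix(i: int, j: int) -> tuple[int, float, tuple[tuple[int, int], ...]]:
        """(-pairs, cost, pairs) of the optimal matching of ref[i:] x tgt[j:]."""
        if i == len(reference) or j == len(shifted):
            return (0, 0.0, ())
        options = [best_suffix(i + 1, j), best_suffix(i, j + 1)]
        lag = abs(reference[i] - shifted[j])
        if lag <= max_lag:
            n, c, p = best_suffix(i + 1, j + 1)
            options.append((n - 1, c + lag, ((i, j),) + p))
        return min(options)

    return list(best_suffix(0, 0)[2])


def grid_search_prepost(
    reference: np.ndarray,
    target: np.ndarray,
    n_pre: int,
    n_post: int,
    a_range: tuple[float, float],
    b_range: tuple[float, float],
    n_grid: int = 201,
) -> tuple[float, float, float]:
    """2-D grid search minimizing |median PRE residual| + |median POST residual|."""
    a_grid = np.linspace(*a_range, n_grid)
    b_grid = np.linspace(*b_range, n_grid)
    r_pre, t_pre = reference[:n_pre], target[:n_pre]
    r_post, t_post = reference[-n_post:], target[-n_post:]
    best = (np.inf, np.nan, np.nan)
    for b in b_grid:
        med_pre = np.median(r_pre[None, :] - b * t_pre[None, :] - a_grid[:, None], axis=1)
        med_post = np.median(r_post[None, :] - b * t_post[None, :] - a_grid[:, None], axis=1)
        score = np.abs(med_pre) + np.abs(med_post)
        k = int(np.argmin(score))
        if score[k] < best[0]:
            best = (float(score[k]), float(a_grid[k]), float(b))
    return best[1], best[2], best[0]


def events(*times: float) -> EventSeries:
    return EventSeries(np.asarray(times, float))
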