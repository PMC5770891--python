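"""Plain-text readers and writers for event series and traces.

Event CSV: a single ``time_s`` column, one onset per row.

Trace CSV, two dialects:

* explicit-time — columns ``time_s,amplitude_mv``; the grid must be uniform;
* implicit-grid — a single ``amplitude_mv`` column plus a JSON sidecar
  ``<trace>.json`` holding ``{"rate_hz": ..., "start_time_s": ..., "label": ...}``.

All floats are written with 17 significant digits so write-then-read round
trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .timeline import EventSeries, SampledTrace

__all__ = [
    "read_events",
    "write_events",
    "read_trace",
    "write_trace",
    "sidecar_path",
    "FormatError",
]

_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Raised on malformed event or trace files."""


def sidecar_path(path: str | Path) -> Path:
    """JSON metadata companion of an implicit-grid trace CSV."""
    return Path(path).with_suffix(".json")


def write_events(series: EventSeries, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": series.times})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def read_events(path: str | Path, clock_label: str = "") -> EventSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: expected a 'time_s' column, found {list(df.columns)}")
    times = df["time_s"].to_numpy(float)
    if times.size and not np.all(np.isfinite(times)):
        bad = int(np.flatnonzero(~np.isfinite(times))[0])
        raise FormatError(f"{path}: non-finite time at row {bad + 2}")
    if times.size > 1:
        diffs = np.diff(times)
        if not np.all(diffs > 0):
            bad = int(np.flatnonzero(diffs <= 0)[0]) + 1
            raise FormatError(
                f"{path}: event times must be strictly increasing; "
                f"violation at row {bad + 2} (time_s={times[bad]!r})"
            )
    return EventSeries(times, clock_label=clock_label)


def write_trace(trace: SampledTrace, path: str | Path, dialect: str = "implicit") -> None:
    path = Path(path)
    if dialect == "explicit":
        df = pd.DataFrame({"time_s": trace.times, "amplitude_mv": trace.values})
        df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    elif dialect == "implicit":
        df = pd.DataFrame({"amplitude_mv": trace.values})
        df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
        meta = {
            "rate_hz": trace.rate_nominal,
            "start_time_s": trace.start_time,
            "label": trace.label,
        }
        sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_trace(path: str | Path, rate: float | None = None) -> SampledTrace:
    """Read either trace dialect; ``rate`` cross-checks the stored rate if given."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "amplitude_mv" not in df.columns:
        raise FormatError(f"{path}: expected an 'amplitude_mv' column, found {list(df.columns)}")
    values = df["amplitude_mv"].to_numpy(float)

    if "time_s" in df.columns:
        times = df["time_s"].to_numpy(float)
        if times.size < 2:
            raise FormatError(f"{path}: explicit-time dialect needs >= 2 samples")
        steps = np.diff(times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise FormatError(f"{path}: explicit-time dialect requires a uniform time grid")
        file_rate = (times.size - 1) / (times[-1] - times[0])
        start = float(times[0])
        label = ""
    else:
        meta_path = sidecar_path(path)
        if not meta_path.exists():
            raise FormatError(
                f"{path}: implicit-grid dialect requires the JSON sidecar {meta_path}"
            )
        meta = json.loads(meta_path.read_text())
        file_rate = float(meta["rate_hz"])
        start = float(meta.get("start_time_s", 0.0))
        label = str(meta.get("label", ""))

    if rate is not None and not np.isclose(rate, file_rate, rtol=1e-9):
        raise FormatError(
            f"{path}: sampling rate mismatch — file declares {file_rate!r} Hz, "
            f"caller requested {rate!r} Hz"
        )
    return SampledTrace(values, rate_nominal=file_rate, start_time=start, label=label)


def read_events_edf(path: str | Path) -> EventSeries:
    """Optional EDF ingest: onset annotations as an event series (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("EDF ingest requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    onsets = np.sort(np.asarray(raw.annotations.onset, float))
    return EventSeries(onsets, clock_label=str(path))


def read_trace_edf(path: str | Path, channel: str) -> SampledTrace:
    """Optional EDF ingest: one named channel as a trace (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("EDF ingest requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    data = raw.get_data(picks=[channel])[0] * 1e3  # V -> mV
    return SampledTrace(data, rate_nominal=float(raw.info["sfreq"]), label=channel)
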