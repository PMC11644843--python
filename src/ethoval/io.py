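"""CSV dialects for label, tilt and weather series.

Label CSV: ``timestamp,<channel>`` with ISO-8601 UTC timestamps and 0/1
labels (empty cell = missing), one row per second or per minute.
Tilt CSV: ``timestamp,tilt_deg``. Weather CSV:
``timestamp,temperature_c,relative_humidity_pct``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .series import (
    BehaviorStream,
    IntervalAggregate,
    MinuteLabelSeries,
    TiltSeries,
    WeatherSeries,
)

__all__ = [
    "write_labels",
    "read_behavior_stream",
    "read_minute_labels",
    "write_tilt",
    "read_tilt",
    "write_weather",
    "read_weather",
    "write_intervals",
]


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    ts = pd.DatetimeIndex(df["timestamp"])
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    df["timestamp"] = ts
    return df


def _channel_column(df: pd.DataFrame) -> str:
    cols = [c for c in df.columns if c != "timestamp"]
    if len(cols) != 1:
        raise ValueError(f"expected exactly one label column, found {cols}")
    return cols[0]


def write_labels(obj: BehaviorStream | MinuteLabelSeries, path) -> None:
    df = obj.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    ch = obj.channel
    df[ch] = df[ch].map(lambda v: "" if np.isnan(v) else str(int(v)))
    df.to_csv(path, index=False)


def _grid_check(ts: pd.DatetimeIndex, step_s: int, what: str) -> None:
    if len(ts) > 1:
        deltas = np.diff(ts.asi8) / 1e9
        if not np.all(deltas == step_s):
            raise ValueError(f"{what} timestamps must be gap-free at {step_s} s spacing")


def read_behavior_stream(path, channel: str | None = None) -> BehaviorStream:
    df = _read_csv(path)
    ch = channel or _channel_column(df)
    ts = pd.DatetimeIndex(df["timestamp"])
    _grid_check(ts, 1, "behavior stream")
    return BehaviorStream(ts[0], df[ch].to_numpy(float), ch)


def read_minute_labels(path, channel: str | None = None) -> MinuteLabelSeries:
    df = _read_csv(path)
    ch = channel or _channel_column(df)
    ts = pd.DatetimeIndex(df["timestamp"])
    _grid_check(ts, 60, "minute label")
    return MinuteLabelSeries(ts[0], df[ch].to_numpy(float), ch)


def write_tilt(tilt: TiltSeries, path) -> None:
    df = tilt.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False, float_format="%.3f")


def read_tilt(path) -> TiltSeries:
    df = _read_csv(path)
    ts = pd.DatetimeIndex(df["timestamp"])
    return TiltSeries(ts[0], df["tilt_deg"].to_numpy(float))


def write_weather(weather: WeatherSeries, path) -> None:
    df = weather.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False, float_format="%.2f")


def read_weather(path) -> WeatherSeries:
    df = _read_csv(path)
    return WeatherSeries(
        pd.DatetimeIndex(df["timestamp"]),
        df["temperature_c"].to_numpy(float),
        df["relative_humidity_pct"].to_numpy(float),
    )


def write_intervals(agg: IntervalAggregate, path) -> None:
    df = agg.to_frame()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    df.to_csv(path, index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
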