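"""Time-series containers shared across the package.

All containers are thin frozen dataclasses around numpy arrays with an
implied regular time grid (1 s for raw streams, 60 s for minute labels).
Labels are stored as float64 in {0.0, 1.0, NaN}; NaN marks a missing
observation and propagates through resampling rather than being imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default recording start used by the simulator (pasture season, UTC).
DEFAULT_START = pd.Timestamp("2024-06-01 00:00:00", tz="UTC")


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=float)
    if labels.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    finite = labels[~np.isnan(labels)]
    if finite.size and not np.isin(finite, (0.0, 1.0)).all():
        raise ValueError("labels must be binary (0/1) or NaN")
    return labels


@dataclass(frozen=True)
class BehaviorStream:
    """Per-second binary labels for one behavior channel.

    ``labels[i]`` covers the second starting at ``start_time + i`` seconds;
    1 means the behavior is present. NaN marks seconds with no usable
    observation (e.g. unreadable tilt samples).
    """

    start_time: pd.Timestamp
    labels: np.ndarray
    channel: str

    resolution_s: int = field(default=1, init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", _validate_labels(self.labels))
        if len(self.labels) == 0:
            raise ValueError("BehaviorStream must contain at least one sample")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self.labels), freq="1s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, self.channel: self.labels})


@dataclass(frozen=True)
class TiltSeries:
    """Raw vertical tilt angle (degrees) sampled at 1 Hz."""

    start_time: pd.Timestamp
    angle: np.ndarray

    def __post_init__(self) -> None:
        angle = np.asarray(self.angle, dtype=float)
        if angle.ndim != 1 or len(angle) == 0:
            raise ValueError("angle must be a non-empty 1-d array")
        object.__setattr__(self, "angle", angle)

    def __len__(self) -> int:
        return len(self.angle)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self.angle), freq="1s")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "tilt_deg": self.angle})


@dataclass(frozen=True)
class MinuteLabelSeries:
    """Per-minute binary labels (predominant behavior), NaN = missing."""

    start_time: pd.Timestamp
    labels: np.ndarray
    channel: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", _validate_labels(self.labels))
        if len(self.labels) == 0:
            raise ValueError("MinuteLabelSeries must contain at least one minute")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self.labels), freq="60s")

    def with_labels(self, labels: np.ndarray) -> "MinuteLabelSeries":
        return replace(self, labels=labels)

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.timestamps, name=self.channel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, self.channel: self.labels})


@dataclass(frozen=True)
class IntervalAggregate:
    """Minutes of behavior per fixed window (default 10 min).

    Only windows fully covered by non-missing minutes are kept, so the
    timestamp index may be gappy; spacing between consecutive entries is
    always a multiple of the window width.
    """

    timestamps: pd.DatetimeIndex
    behavior_minutes: np.ndarray
    width_min: int
    channel: str

    def __post_init__(self) -> None:
        minutes = np.asarray(self.behavior_minutes, dtype=float)
        if len(minutes) != len(self.timestamps):
            raise ValueError("timestamps and behavior_minutes lengths differ")
        if minutes.size and (minutes.min() < 0 or minutes.max() > self.width_min):
            raise ValueError("behavior_minutes must lie in [0, width]")
        object.__setattr__(self, "behavior_minutes", minutes)

    def __len__(self) -> int:
        return len(self.behavior_minutes)

    def to_series(self) -> pd.Series:
        return pd.Series(self.behavior_minutes, index=self.timestamps, name=self.channel)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, self.channel: self.behavior_minutes}
        )


@dataclass(frozen=True)
class WeatherSeries:
    """Ambient temperature (°C) and relative humidity (%) at 10-min cadence."""

    timestamps: pd.DatetimeIndex
    temperature_c: np.ndarray
    relative_humidity_pct: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature_c, dtype=float)
        rh = np.asarray(self.relative_humidity_pct, dtype=float)
        if not (len(t) == len(rh) == len(self.timestamps)):
            raise ValueError("weather arrays must share one length")
        if rh.size and (np.nanmin(rh) < 0 or np.nanmax(rh) > 100):
            raise ValueError("relative humidity must lie in [0, 100]")
        if not self.timestamps.is_monotonic_increasing:
            raise ValueError("weather timestamps must be increasing")
        object.__setattr__(self, "temperature_c", t)
        object.__setattr__(self, "relative_humidity_pct", rh)

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "temperature_c": self.temperature_c,
                "relative_humidity_pct": self.relative_humidity_pct,
            }
        )


@dataclass(frozen=True)
class MergedDataset:
    """Timestamp-aligned sources (gold standard plus sensors) at one resolution.

    Rows are the outer join of all source timestamps; a NaN cell means that
    source is missing there. Every pairwise statistic is computed only over
    rows where both members are non-missing.
    """

    data: pd.DataFrame
    resolution: str  # "1min" | "10min"

    @property
    def sources(self) -> list[str]:
        return list(self.data.columns)

    def pair(self, a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise-complete value arrays for sources ``a`` and ``b``."""
        sub = self.data[[a, b]].dropna()
        return sub[a].to_numpy(float), sub[b].to_numpy(float)

    def pair_n(self, a: str, b: str) -> int:
        return int(self.data[[a, b]].dropna().shape[0])

    def subset(self, mask: np.ndarray | pd.Series) -> "MergedDataset":
        return MergedDataset(self.data.loc[mask], self.resolution)
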