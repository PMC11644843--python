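"""Resampling and alignment of behavior label series.

1-s streams are reduced to 1-min labels by the predominant-behavior rule
(a minute is positive iff >= 30 of its 60 seconds are positive; the exact
30/30 tie goes to the positive class by default). Minute labels are summed
into fixed windows (default 10 min) of minutes-of-behavior; a window with
any missing minute is dropped rather than prorated, mirroring how short
video observation windows are handled. Multiple sources are outer-joined
on timestamp so each pairwise comparison uses its own complete rows.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .series import BehaviorStream, IntervalAggregate, MergedDataset, MinuteLabelSeries

__all__ = ["to_minutes", "to_intervals", "merge_sources"]


def to_minutes(stream: BehaviorStream, tie_positive: bool = True) -> MinuteLabelSeries:
    """Predominant-behavior 1-min labels from a 1-s stream.

    Only complete minutes (60 samples, all observed) are labeled; a trailing
    partial minute or a minute containing a missing second becomes NaN.
    ``tie_positive`` controls the label at exactly 30/30 seconds.
    """
    labels = np.asarray(stream.labels, dtype=float)
    n_full, rem = divmod(len(labels), 60)
    n_min = n_full + (1 if rem else 0)
    out = np.full(n_min, np.nan)
    if n_full:
        block = labels[: n_full * 60].reshape(n_full, 60)
        seconds_on = block.sum(axis=1)  # NaN if any second missing
        with np.errstate(invalid="ignore"):
            pos = seconds_on >= 30 if tie_positive else seconds_on > 30
        ok = ~np.isnan(seconds_on)
        out[:n_full][ok] = pos[ok].astype(float)
    return MinuteLabelSeries(stream.start_time, out, stream.channel)


def to_intervals(minutes: MinuteLabelSeries, width: int = 10) -> IntervalAggregate:
    """Minutes-of-behavior per half-open window [t, t + width min).

    Windows are aligned to the series start; any window containing a missing
    minute (or only partially covered at the tail) is dropped.
    """
    if width < 1 or int(width) != width:
        raise ValueError("width must be a positive integer number of minutes")
    width = int(width)
    labels = np.asarray(minutes.labels, dtype=float)
    n_win = len(labels) // width
    ts = minutes.timestamps
    if n_win == 0:
        return IntervalAggregate(
            pd.DatetimeIndex([], tz=ts.tz), np.array([]), width, minutes.channel
        )
    block = labels[: n_win * width].reshape(n_win, width)
    sums = block.sum(axis=1)
    keep = ~np.isnan(sums)
    starts = ts[np.arange(n_win) * width][keep]
    return IntervalAggregate(starts, sums[keep], width, minutes.channel)


def _as_series(obj: MinuteLabelSeries | IntervalAggregate) -> tuple[pd.Series, str]:
    if isinstance(obj, MinuteLabelSeries):
        return obj.to_series().dropna(), "1min"
    if isinstance(obj, IntervalAggregate):
        return obj.to_series(), f"{obj.width_min}min"
    raise TypeError(f"cannot merge object of type {type(obj).__name__}")


def merge_sources(
    sources: Mapping[str, MinuteLabelSeries | IntervalAggregate],
) -> MergedDataset:
    """Outer-join sources on timestamp into one aligned dataset.

    All sources must share a resolution; missing rows stay NaN so that
    per-pair sample sizes reflect each pair's own data losses.
    """
    if not sources:
        raise ValueError("merge_sources needs at least one source")
    columns: dict[str, pd.Series] = {}
    resolutions = set()
    for name, obj in sources.items():
        s, res = _as_series(obj)
        resolutions.add(res)
        columns[name] = s
    if len(resolutions) != 1:
        raise ValueError(f"mixed resolutions cannot be aligned: {sorted(resolutions)}")
    df = pd.concat(columns, axis=1, join="outer").sort_index()
    df.index.name = "timestamp"
    return MergedDataset(df, resolutions.pop())
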