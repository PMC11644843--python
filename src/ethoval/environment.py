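"""Temperature–humidity index (THI) and heat-stress stratification.

THI combines ambient temperature T (°C) and relative humidity RH (%) into a
single heat-load index:

    THI = (1.8 T + 32) - (0.55 - 0.0055 RH) (1.8 T - 26)

At 1.8 T = 26 (T ≈ 14.44 °C) the humidity term vanishes and THI = 58 for
every RH; above that point THI increases with both T and RH. Dairy cows can
show heat-stress signs from THI >= 68, which is the default threshold for
splitting a 10-min evaluation dataset into a thermoneutral and a heat-load
stratum. The coefficient set is exposed so alternative THI variants can be
swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import agreement
from .series import MergedDataset, WeatherSeries

__all__ = ["thi", "ThiFormula", "StratificationResult", "stratify"]

HEAT_STRESS_THI = 68.0


@dataclass(frozen=True)
class ThiFormula:
    """THI = (a·T + b) − (c − d·RH)·(a·T − e)."""

    a: float = 1.8
    b: float = 32.0
    c: float = 0.55
    d: float = 0.0055
    e: float = 26.0

    def __call__(self, temperature_c, relative_humidity_pct):
        t = np.asarray(temperature_c, dtype=float)
        rh = np.asarray(relative_humidity_pct, dtype=float)
        if np.any((rh < 0) | (rh > 100)):
            raise ValueError("relative humidity must lie in [0, 100]")
        out = (self.a * t + self.b) - (self.c - self.d * rh) * (self.a * t - self.e)
        return out if out.ndim else float(out)


def thi(temperature_c, relative_humidity_pct, formula: ThiFormula = ThiFormula()):
    """Temperature–humidity index; scalar in, scalar out."""
    return formula(temperature_c, relative_humidity_pct)


@dataclass(frozen=True)
class StratificationResult:
    below: MergedDataset
    at_or_above: MergedDataset
    metrics_below: pd.DataFrame
    metrics_at_or_above: pd.DataFrame
    threshold: float
    n_excluded: int  # intervals with no weather record within tolerance

    @property
    def stratum_sizes(self) -> tuple[int, int]:
        return len(self.below.data), len(self.at_or_above.data)


def stratify(
    merged: MergedDataset,
    weather: WeatherSeries,
    gold: str,
    threshold: float = HEAT_STRESS_THI,
    tolerance_min: int = 10,
    formula: ThiFormula = ThiFormula(),
) -> StratificationResult:
    """Split a 10-min dataset at the THI threshold and evaluate each stratum.

    Each interval is matched to the nearest preceding weather record within
    ``tolerance_min`` minutes; unmatched intervals are excluded (their count
    is reported). Pooling the two strata reproduces the covered row set, so
    recomputing metrics on the pooled rows equals the unstratified result.
    Empty strata yield metrics frames with NaN/absent rows rather than an
    error.
    """
    thi_vals = formula(weather.temperature_c, weather.relative_humidity_pct)
    wx = pd.DataFrame({"timestamp": weather.timestamps, "thi": thi_vals})
    left = pd.DataFrame({"timestamp": merged.data.index})
    matched = pd.merge_asof(
        left,
        wx,
        on="timestamp",
        direction="backward",
        tolerance=pd.Timedelta(minutes=tolerance_min),
    )
    thi_per_row = matched["thi"].to_numpy()
    covered = ~np.isnan(thi_per_row)
    below = merged.subset(covered & (thi_per_row < threshold))
    above = merged.subset(covered & (thi_per_row >= threshold))

    def _metrics(ds: MergedDataset) -> pd.DataFrame:
        if len(ds.data) < 2:
            cols = [c for c in ds.sources if c != gold]
            return pd.DataFrame(
                [agreement.AgreementMetrics(source=c).as_dict() for c in cols]
            ).set_index("source") if cols else pd.DataFrame()
        return agreement.evaluate(ds, gold=gold)

    return StratificationResult(
        below=below,
        at_or_above=above,
        metrics_below=_metrics(below),
        metrics_at_or_above=_metrics(above),
        threshold=threshold,
        n_excluded=int((~covered).sum()),
    )
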