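"""Synthetic cow-behavior, tilt and weather generator.

Behavior is modeled as an alternating-renewal process per channel: bouts
(runs of 1) and gaps (runs of 0) with durations drawn from configurable
positive distributions. Defaults emulate grazing dairy cows as observed by
drone video: rumination ~12% of the time in bouts of median 30 min, lying
~25% in bouts of median 45 min. Rumination preferentially starts while the
cow is lying (configurable coupling multiplier on the bout-start hazard).

Sensor degradation is applied at the 1-min label level via
:func:`corrupt_minutes` (spurious isolated minutes, whole-bout misses,
boundary jitter) and at the 1-s tilt level via :func:`simulate_tilt`
(Gaussian noise plus brief kick excursions across the lying threshold).

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import (
    DEFAULT_START,
    BehaviorStream,
    MinuteLabelSeries,
    TiltSeries,
    WeatherSeries,
)

__all__ = [
    "DurationDistribution",
    "ChannelConfig",
    "SimulationConfig",
    "SensorErrorModel",
    "simulate_behavior",
    "simulate_tilt",
    "corrupt_minutes",
    "simulate_weather",
]

#: Tilt set-points (degrees of vertical tilt), far from the 60° threshold so
#: the noise-free round trip through the classifier is exact.
LYING_TILT_DEG = 90.0
STANDING_TILT_DEG = 20.0


class ConfigurationError(ValueError):
    """Raised for invalid simulator configuration."""


@dataclass(frozen=True)
class DurationDistribution:
    """Named positive duration distribution (minutes)."""

    name: str
    params: dict

    @classmethod
    def lognormal(cls, median_min: float, sigma: float) -> "DurationDistribution":
        if median_min <= 0 or sigma < 0:
            raise ConfigurationError("lognormal needs median_min > 0, sigma >= 0")
        return cls("lognormal", {"median_min": float(median_min), "sigma": float(sigma)})

    @classmethod
    def exponential(cls, mean_min: float) -> "DurationDistribution":
        if mean_min <= 0:
            raise ConfigurationError("exponential needs mean_min > 0")
        return cls("exponential", {"mean_min": float(mean_min)})

    @classmethod
    def fixed(cls, minutes: float) -> "DurationDistribution":
        if minutes <= 0:
            raise ConfigurationError("fixed duration must be > 0")
        return cls("fixed", {"minutes": float(minutes)})

    def mean(self) -> float:
        if self.name == "lognormal":
            return self.params["median_min"] * math.exp(self.params["sigma"] ** 2 / 2)
        if self.name == "exponential":
            return self.params["mean_min"]
        if self.name == "fixed":
            return self.params["minutes"]
        raise ConfigurationError(f"unknown distribution {self.name!r}")

    def sample(self, rng: np.random.Generator) -> float:
        """One duration draw, in minutes (> 0)."""
        if self.name == "lognormal":
            mu = math.log(self.params["median_min"])
            return float(rng.lognormal(mu, self.params["sigma"]))
        if self.name == "exponential":
            return float(rng.exponential(self.params["mean_min"]))
        if self.name == "fixed":
            return self.params["minutes"]
        raise ConfigurationError(f"unknown distribution {self.name!r}")


@dataclass(frozen=True)
class ChannelConfig:
    """Alternating-renewal parameters for one behavior channel.

    If ``gap_duration_dist`` is None, gaps default to a log-normal with the
    bout distribution's sigma and a mean chosen so the long-run prevalence
    E[bout] / (E[bout] + E[gap]) equals ``target_prevalence``.

    ``lying_coupling`` multiplies the bout-start hazard while the cow is
    lying; with a value other than 1 the gap durations follow a
    state-modulated exponential hazard instead of ``gap_duration_dist``.
    """

    bout_duration_dist: DurationDistribution
    target_prevalence: float
    gap_duration_dist: DurationDistribution | None = None
    lying_coupling: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 1:
            raise ConfigurationError("target_prevalence must lie in (0, 1)")
        if self.lying_coupling < 0:
            raise ConfigurationError("lying_coupling must be >= 0")

    def gap_mean(self) -> float:
        b = self.bout_duration_dist.mean()
        return b * (1 - self.target_prevalence) / self.target_prevalence

    def effective_gap_dist(self) -> DurationDistribution:
        if self.gap_duration_dist is not None:
            return self.gap_duration_dist
        sigma = self.bout_duration_dist.params.get("sigma", 0.5)
        mean = self.gap_mean()
        median = mean / math.exp(sigma**2 / 2)
        return DurationDistribution.lognormal(median, sigma)


def default_channels() -> dict[str, ChannelConfig]:
    """Study-condition defaults: rumination 12%, lying 25% of time."""
    return {
        "lying": ChannelConfig(
            bout_duration_dist=DurationDistribution.lognormal(45.0, 0.5),
            target_prevalence=0.25,
        ),
        "rumination": ChannelConfig(
            bout_duration_dist=DurationDistribution.lognormal(30.0, 0.5),
            target_prevalence=0.12,
            lying_coupling=2.0,
        ),
    }


@dataclass(frozen=True)
class SimulationConfig:
    duration_s: int
    seed: int
    channels: dict[str, ChannelConfig] = field(default_factory=default_channels)
    start_time: pd.Timestamp = DEFAULT_START

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be > 0")
        if not self.channels:
            raise ConfigurationError("at least one channel is required")


@dataclass(frozen=True)
class SensorErrorModel:
    """Minute-level sensor error modes.

    spurious_minute_rate: expected isolated false-positive minutes per hour
    (misclassification of e.g. eating as rumination); bout_miss_prob:
    probability an entire true bout is dropped; boundary_jitter_sd: SD in
    minutes of the rounded-Gaussian shift applied to each bout boundary.
    """

    spurious_minute_rate: float = 0.0
    bout_miss_prob: float = 0.0
    boundary_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spurious_minute_rate < 0:
            raise ConfigurationError("spurious_minute_rate must be >= 0")
        if not 0 <= self.bout_miss_prob <= 1:
            raise ConfigurationError("bout_miss_prob must lie in [0, 1]")
        if self.boundary_jitter_sd < 0:
            raise ConfigurationError("boundary_jitter_sd must be >= 0")


def _channel_rng(seed: int, channel: str) -> np.random.Generator:
    # stable per-channel substream independent of simulation order
    key = int.from_bytes(channel.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _renewal_labels(
    n_s: int,
    bout_dist: DurationDistribution,
    gap_dist: DurationDistribution,
    p0: float,
    rng: np.random.Generator,
) -> np.ndarray:
    labels = np.zeros(n_s)
    t = 0
    in_bout = bool(rng.random() < p0)
    while t < n_s:
        dist = bout_dist if in_bout else gap_dist
        dur_s = max(1, round(dist.sample(rng) * 60))
        if in_bout:
            labels[t : t + dur_s] = 1.0
        t += dur_s
        in_bout = not in_bout
    return labels


def _coupled_labels(
    n_s: int,
    cfg: ChannelConfig,
    lying: np.ndarray,
    lying_prevalence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Renewal process whose gap hazard is multiplied while lying.

    The base hazard is calibrated so the *marginal* mean gap matches the
    prevalence target: lambda0 = 1 / (G * mbar) with mbar the mean hazard
    multiplier under the lying channel's target prevalence.
    """
    c = cfg.lying_coupling
    mbar = 1.0 + (c - 1.0) * lying_prevalence
    if mbar <= 0:
        raise ConfigurationError("coupling yields non-positive mean hazard")
    lam0_per_s = 1.0 / (cfg.gap_mean() * mbar * 60.0)
    mult = np.where(lying > 0, c, 1.0)
    cumhaz = np.cumsum(lam0_per_s * mult)

    labels = np.zeros(n_s)
    t = 0
    in_bout = bool(rng.random() < cfg.target_prevalence)
    while t < n_s:
        if in_bout:
            dur_s = max(1, round(cfg.bout_duration_dist.sample(rng) * 60))
            labels[t : t + dur_s] = 1.0
            t += dur_s
        else:
            e = rng.exponential(1.0)
            base = cumhaz[t - 1] if t > 0 else 0.0
            j = int(np.searchsorted(cumhaz, base + e))
            t = max(j, t + 1)  # gap of at least 1 s
        in_bout = not in_bout
    return labels


def simulate_behavior(config: SimulationConfig) -> dict[str, BehaviorStream]:
    """Simulate a gold-standard 1-s binary stream per behavior channel.

    "lying" is simulated first so channels with ``lying_coupling != 1`` can
    condition their bout-start hazard on the lying state. Deterministic
    under ``config.seed``; each channel uses an independent substream, so
    adding a channel never perturbs the others.
    """
    n_s = int(config.duration_s)
    streams: dict[str, BehaviorStream] = {}
    order = sorted(config.channels, key=lambda ch: (ch != "lying", ch))
    lying_labels: np.ndarray | None = None
    lying_prev = config.channels.get(
        "lying", ChannelConfig(DurationDistribution.fixed(1.0), 0.5)
    ).target_prevalence
    for channel in order:
        cfg = config.channels[channel]
        rng = _channel_rng(config.seed, channel)
        if cfg.lying_coupling != 1.0 and lying_labels is not None:
            labels = _coupled_labels(n_s, cfg, lying_labels, lying_prev, rng)
        else:
            labels = _renewal_labels(
                n_s,
                cfg.bout_duration_dist,
                cfg.effective_gap_dist(),
                cfg.target_prevalence,
                rng,
            )
        if channel == "lying":
            lying_labels = labels
        streams[channel] = BehaviorStream(config.start_time, labels, channel)
    return streams


def simulate_tilt(
    lying: BehaviorStream,
    noise_sd: float = 0.0,
    kick_rate: float = 0.0,
    seed: int = 0,
) -> TiltSeries:
    """Raw 1 Hz vertical tilt for a leg-mounted logger.

    Lying seconds sit at 90°, standing at 20° (both far from the 60°
    classification threshold), plus i.i.d. Gaussian noise. Kick events occur
    at ``kick_rate`` per hour; each replaces a brief (5-45 s) window with
    the opposite set-point, crossing the threshold.
    """
    if noise_sd < 0 or kick_rate < 0:
        raise ConfigurationError("noise_sd and kick_rate must be >= 0")
    rng = np.random.default_rng(seed)
    base = np.asarray(lying.labels, dtype=float)
    angle = np.where(base > 0, LYING_TILT_DEG, STANDING_TILT_DEG)
    n = len(angle)
    n_kicks = rng.poisson(kick_rate * n / 3600.0)
    for _ in range(n_kicks):
        start = int(rng.integers(0, n))
        dur = int(rng.integers(5, 46))
        sl = slice(start, min(start + dur, n))
        flipped = np.where(
            angle[sl] > 60.0, STANDING_TILT_DEG, LYING_TILT_DEG
        )
        angle[sl] = flipped
    if noise_sd > 0:
        angle = angle + rng.normal(0.0, noise_sd, size=n)
    return TiltSeries(lying.start_time, angle)


def _runs_of_ones(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(starts, ends) of maximal runs of 1 (end exclusive)."""
    padded = np.concatenate(([0.0], x, [0.0]))
    diff = np.diff(padded)
    return np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)


def corrupt_minutes(
    truth: MinuteLabelSeries,
    model: SensorErrorModel,
    rate_weights: np.ndarray | None = None,
) -> MinuteLabelSeries:
    """Apply sensor error modes to a 1-min gold-standard label series.

    Order of operations: boundary jitter (rounded Gaussian shift of each
    bout's start and end, clipped to the window), whole-bout deletion, then
    spurious isolated positive minutes on remaining zero minutes.
    ``rate_weights`` optionally scales the per-minute spurious intensity
    (e.g. to make misclassification heat-dependent); it must align with the
    series. Missing minutes stay missing and never receive insertions.
    """
    rng = np.random.default_rng(model.seed)
    orig = np.asarray(truth.labels, dtype=float)
    n = len(orig)
    missing = np.isnan(orig)
    base = np.where(missing, 0.0, orig)

    starts, ends = _runs_of_ones(base)
    k = len(starts)
    out = np.zeros(n)
    if k:
        if model.boundary_jitter_sd > 0:
            jit = np.round(rng.normal(0.0, model.boundary_jitter_sd, size=(k, 2)))
        else:
            jit = np.zeros((k, 2))
        miss = rng.random(k) < model.bout_miss_prob if model.bout_miss_prob > 0 else np.zeros(k, bool)
        for i in range(k):
            if miss[i]:
                continue
            s = int(np.clip(starts[i] + jit[i, 0], 0, n))
            e = int(np.clip(ends[i] + jit[i, 1], 0, n))
            if e > s:
                out[s:e] = 1.0

    if model.spurious_minute_rate > 0:
        p = np.full(n, model.spurious_minute_rate / 60.0)
        if rate_weights is not None:
            w = np.asarray(rate_weights, dtype=float)
            if len(w) != n:
                raise ConfigurationError("rate_weights must align with the series")
            p = p * w
        eligible = (out == 0.0) & ~missing
        hits = (rng.random(n) < np.clip(p, 0.0, 1.0)) & eligible
        out[hits] = 1.0

    out[missing] = np.nan
    return truth.with_labels(out)


def simulate_weather(
    duration_h: float,
    mean_temp: float = 18.0,
    amplitude: float = 8.0,
    mean_rh: float = 65.0,
    seed: int = 0,
    rh_amplitude: float | None = None,
    noise_sd: float = 0.5,
    start_time: pd.Timestamp = DEFAULT_START,
) -> WeatherSeries:
    """Sinusoidal diurnal temperature with noise, anti-phase humidity.

    10-min cadence; temperature peaks at 15:00 local (= UTC here). Humidity
    is clipped to [0, 100]. Deterministic under ``seed``.
    """
    if not 0 <= mean_rh <= 100:
        raise ConfigurationError("mean_rh must lie in [0, 100]")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    n = int(round(duration_h * 6))
    if n <= 0:
        raise ConfigurationError("duration_h must cover at least one 10-min step")
    rng = np.random.default_rng(seed)
    ts = pd.date_range(start_time, periods=n, freq="10min")
    hour = ts.hour + ts.minute / 60.0
    phase = np.sin(2 * np.pi * (hour - 9.0) / 24.0)  # peak at 15:00
    temp = mean_temp + amplitude * phase
    if rh_amplitude is None:
        rh_amplitude = 1.5 * amplitude
    rh = mean_rh - rh_amplitude * phase
    if noise_sd > 0:
        temp = temp + rng.normal(0.0, noise_sd, size=n)
        rh = rh + rng.normal(0.0, 2.0 * noise_sd, size=n)
    rh = np.clip(rh, 0.0, 100.0)
    return WeatherSeries(ts, temp, rh)
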