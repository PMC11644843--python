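"""End-to-end orchestration: simulate → classify → resample → correct →
evaluate → stratify, from a single YAML config with reproducible seeding.

Sensors are declared in the config as either minute-label corrupters
(ear-tag / noseband style, ``kind: corrupt``) or tilt-route loggers
(``kind: tilt``: 1 Hz tilt synthesis, threshold classification, then
minute resampling). Every sensor is evaluated raw and after the correction
algorithm (suffix ``+CA``) against the simulated gold standard ("ivo").

A single top-level seed deterministically derives per-stage seeds by
hashing the stage name, so adding a sensor or stage never perturbs the
randomness of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, environment, io
from .classify import TiltThresholdRule, classify_tilt
from .correction import CorrectionPolicy, apply_ca
from .series import MergedDataset, MinuteLabelSeries
from .simulate import (
    ChannelConfig,
    DurationDistribution,
    SensorErrorModel,
    SimulationConfig,
    corrupt_minutes,
    simulate_behavior,
    simulate_tilt,
    simulate_weather,
)
from .temporal import merge_sources, to_intervals, to_minutes

__all__ = ["RunManifest", "run_pipeline", "load_config", "default_config", "stage_seed", "GOLD"]

GOLD = "ivo"  # gold-standard column name: indirect visual observation

log = logging.getLogger("ethoval.pipeline")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the run seed and stage name."""
    digest = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def default_config() -> dict:
    """Study-condition defaults: 200 h herd-time, three sensor archetypes."""
    return {
        "seed": 0,
        "duration_hours": 200,
        "channels": {
            "lying": {"bout_median_min": 45.0, "bout_sigma": 0.5, "target_prevalence": 0.25},
            "rumination": {
                "bout_median_min": 30.0,
                "bout_sigma": 0.5,
                "target_prevalence": 0.12,
                "lying_coupling": 2.0,
            },
        },
        "sensors": {
            "ear_tag": {
                "kind": "corrupt",
                "channels": ["rumination", "lying"],
                "spurious_minute_rate": 0.5,
                "bout_miss_prob": 0.05,
                "boundary_jitter_sd": 1.0,
            },
            "noseband": {
                "kind": "corrupt",
                "channels": ["rumination"],
                "spurious_minute_rate": 2.0,
                "bout_miss_prob": 0.02,
                "boundary_jitter_sd": 1.0,
            },
            "leg_logger": {
                "kind": "tilt",
                "channels": ["lying"],
                "noise_sd": 5.0,
                "kick_rate": 2.0,
            },
        },
        "correction": {"max_run_to_remove": 2, "symmetric": True},
        "weather": {"mean_temp_c": 18.0, "amplitude_c": 8.0, "mean_rh_pct": 65.0},
        "evaluation": {"interval_min": 10, "thi_threshold": 68.0},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    merged = default_config()
    merged.update(cfg)
    return merged


def _channel_config(d: dict) -> ChannelConfig:
    return ChannelConfig(
        bout_duration_dist=DurationDistribution.lognormal(
            d.get("bout_median_min", 30.0), d.get("bout_sigma", 0.5)
        ),
        target_prevalence=d["target_prevalence"],
        lying_coupling=d.get("lying_coupling", 1.0),
    )


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "counts": self.counts,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> RunManifest:
    """Run the full validation chain and write reports under ``out_dir``.

    Deterministic: identical config + seed produce byte-identical reports.
    Returns a manifest with per-stage row counts and exclusions.
    """
    out = io.ensure_dir(out_dir)
    cfg = dict(config)
    if seed is not None:
        cfg["seed"] = seed
    run_seed = int(cfg["seed"])
    cfg_hash = hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, seed=run_seed)
    policy = CorrectionPolicy(
        max_run_to_remove=cfg["correction"]["max_run_to_remove"],
        symmetric=cfg["correction"]["symmetric"],
    )
    width = int(cfg["evaluation"]["interval_min"])

    def _stage(name):
        t0 = time.perf_counter()
        log.info("stage %s starting", name)
        return t0

    def _done(name, t0):
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    try:
        # --- simulate gold standard ------------------------------------
        t0 = _stage("simulate")
        duration_s = int(cfg["duration_hours"] * 3600)
        sim = SimulationConfig(
            duration_s=duration_s,
            seed=stage_seed(run_seed, "behavior"),
            channels={k: _channel_config(v) for k, v in cfg["channels"].items()},
        )
        gold_streams = simulate_behavior(sim)
        gold_minutes = {ch: to_minutes(s) for ch, s in gold_streams.items()}
        for ch, m in gold_minutes.items():
            manifest.counts[f"gold_{ch}_minutes"] = len(m)
            manifest.counts[f"gold_{ch}_missing_minutes"] = int(np.isnan(m.labels).sum())
            path = out / f"gold_{ch}_1min.csv"
            io.write_labels(m, path)
            manifest.outputs.append(path.name)
        _done("simulate", t0)

        # --- sensors ----------------------------------------------------
        t0 = _stage("sensors")
        sensor_minutes: dict[str, dict[str, MinuteLabelSeries]] = {ch: {} for ch in gold_minutes}
        for name, scfg in cfg["sensors"].items():
            for ch in scfg["channels"]:
                if scfg["kind"] == "corrupt":
                    model = SensorErrorModel(
                        spurious_minute_rate=scfg.get("spurious_minute_rate", 0.0),
                        bout_miss_prob=scfg.get("bout_miss_prob", 0.0),
                        boundary_jitter_sd=scfg.get("boundary_jitter_sd", 0.0),
                        seed=stage_seed(run_seed, f"sensor:{name}:{ch}"),
                    )
                    raw = corrupt_minutes(gold_minutes[ch], model)
                elif scfg["kind"] == "tilt":
                    tilt = simulate_tilt(
                        gold_streams[ch],
                        noise_sd=scfg.get("noise_sd", 0.0),
                        kick_rate=scfg.get("kick_rate", 0.0),
                        seed=stage_seed(run_seed, f"sensor:{name}:{ch}"),
                    )
                    raw = to_minutes(classify_tilt(tilt, TiltThresholdRule()))
                else:
                    raise StageError(f"sensors: unknown sensor kind {scfg['kind']!r}")
                sensor_minutes[ch][name] = raw
                sensor_minutes[ch][f"{name}+CA"] = apply_ca(raw, policy)
                io.write_labels(raw, out / f"{name}_{ch}_1min.csv")
                manifest.outputs.append(f"{name}_{ch}_1min.csv")
        _done("sensors", t0)

        # --- 1-min evaluation -------------------------------------------
        t0 = _stage("evaluate_1min")
        reports_1min = []
        for ch, sensors in sensor_minutes.items():
            if not sensors:
                continue
            merged = merge_sources({GOLD: gold_minutes[ch], **sensors})
            df = agreement.evaluate(merged, gold=GOLD)
            df.insert(0, "channel", ch)
            reports_1min.append(df)
            for s in sensors:
                manifest.counts[f"n_1min_{ch}_{s}"] = merged.pair_n(GOLD, s)
        report_1min = pd.concat(reports_1min)
        report_1min.to_csv(out / "report_1min.csv")
        manifest.outputs.append("report_1min.csv")
        _done("evaluate_1min", t0)

        # --- 10-min evaluation ------------------------------------------
        t0 = _stage("evaluate_10min")
        merged_10: dict[str, MergedDataset] = {}
        reports_10 = []
        for ch, sensors in sensor_minutes.items():
            if not sensors:
                continue
            aggs = {GOLD: to_intervals(gold_minutes[ch], width)}
            for s, m in sensors.items():
                aggs[s] = to_intervals(m, width)
                manifest.counts[f"intervals_{ch}_{s}"] = len(aggs[s])
            merged_10[ch] = merge_sources(aggs)
            manifest.counts[f"intervals_merged_{ch}"] = len(merged_10[ch].data)
            df = agreement.evaluate(merged_10[ch], gold=GOLD)
            df.insert(0, "channel", ch)
            reports_10.append(df)
        report_10 = pd.concat(reports_10)
        report_10.to_csv(out / "report_10min.csv")
        manifest.outputs.append("report_10min.csv")
        _done("evaluate_10min", t0)

        # --- weather + THI stratification -------------------------------
        t0 = _stage("stratify")
        wcfg = cfg["weather"]
        weather = simulate_weather(
            duration_h=cfg["duration_hours"],
            mean_temp=wcfg["mean_temp_c"],
            amplitude=wcfg["amplitude_c"],
            mean_rh=wcfg["mean_rh_pct"],
            seed=stage_seed(run_seed, "weather"),
        )
        io.write_weather(weather, out / "weather.csv")
        manifest.outputs.append("weather.csv")
        thr = float(cfg["evaluation"]["thi_threshold"])
        strat_rows = []
        for ch, merged in merged_10.items():
            res = environment.stratify(merged, weather, gold=GOLD, threshold=thr)
            n_lo, n_hi = res.stratum_sizes
            manifest.counts[f"thi_below_{ch}"] = n_lo
            manifest.counts[f"thi_at_or_above_{ch}"] = n_hi
            manifest.counts[f"thi_excluded_{ch}"] = res.n_excluded
            for label, mdf in (
                ("<thr", res.metrics_below),
                (">=thr", res.metrics_at_or_above),
            ):
                if mdf.empty:
                    continue
                mdf = mdf.copy()
                mdf.insert(0, "channel", ch)
                mdf.insert(1, "thi_stratum", label)
                strat_rows.append(mdf)
        report_thi = pd.concat(strat_rows) if strat_rows else pd.DataFrame()
        report_thi.to_csv(out / "report_thi.csv")
        manifest.outputs.append("report_thi.csv")
        _done("stratify", t0)

        # --- plain-text tables + manifest -------------------------------
        with open(out / "report_1min.txt", "w") as fh:
            for ch in sensor_minutes:
                fh.write(f"== {ch} (1 min) ==\n")
                fh.write(
                    agreement.format_report(
                        report_1min[report_1min["channel"] == ch], "1min"
                    )
                )
                fh.write("\n\n")
        with open(out / "report_10min.txt", "w") as fh:
            for ch in merged_10:
                fh.write(f"== {ch} ({width} min) ==\n")
                fh.write(
                    agreement.format_report(report_10[report_10["channel"] == ch], "10min")
                )
                fh.write("\n\n")
        manifest.outputs.extend(["report_1min.txt", "report_10min.txt", "manifest.json"])
        (out / "manifest.json").write_text(manifest.to_json())
    except StageError:
        raise
    except Exception as exc:  # name the failing stage for the operator
        raise StageError(f"pipeline failed: {exc}") from exc
    return manifest


def plot_agreement(merged: MergedDataset, gold: str, path) -> None:
    """Optional scatter of sensor vs. gold 10-min values with regression lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    lims = [0, 10]
    for name in merged.sources:
        if name == gold:
            continue
        x, y = merged.pair(gold, name)
        if len(x) < 2:
            continue
        ax.scatter(x, y, s=8, alpha=0.4, label=name)
        slope, intercept = np.polyfit(x, y, 1)
        xs = np.linspace(lims[0], lims[1], 2)
        ax.plot(xs, slope * xs + intercept, lw=1)
    ax.plot(lims, lims, "k--", lw=1, label="bisector")
    ax.set_xlabel("gold standard (min / interval)")
    ax.set_ylabel("sensor (min / interval)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _configure_logging() -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
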