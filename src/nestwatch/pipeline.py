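"""Configuration and end-to-end orchestration.

A :class:`PipelineConfig` (usually loaded from YAML) declares either a
detection-stream input (plus farrowing labels) or a simulator block, the
analysis frame rate(s), and the smoothing/alarm parameters.  All of the
procedure's constants — the 24 h smoothing window, 15 min step, 48 h
initial alarm interval, the 1.96 confidence multiplier and the supported
rate set — are configuration defaults, never hard-coded downstream.

:func:`run_pipeline` produces, under ``out_dir``:

* ``smoothed_<sow>.csv`` — the smoothed activity series per sow;
* ``trend_<sow>.csv``    — the full-series trend estimate with bounds;
* ``alarms.csv``         — the two-stage alarm report;
* ``evaluation.json``    — cohort summary (when labels are available);
* ``manifest.json``      — config hash, seed and package version.

Identical config + seed give byte-identical artifacts.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .activity import RATE_INTERVALS
from .alarms import AlarmConfig, AlarmOutcome
from .detections_io import (
    FarrowingEvent,
    read_detection_stream,
    read_farrowing_labels,
    write_alarm_report,
    write_activity_series,
)
from .errors import ConfigurationError, ValidationError
from .evaluation import classify, cohort_summary, frame_rate_sweep, run_sow_pipeline
from .kalmsmo import IRWParams, irw_smooth
from .synthetic import SimConfig, iter_cohort

__all__ = ["PipelineConfig", "run_pipeline", "load_cohort", "write_trend_estimate"]

logger = logging.getLogger("nestwatch")

HOUR = 3600.0


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    seed: int = 0
    out_dir: str = "nestwatch_out"
    log_level: str = "INFO"
    rate: str = "1fps"
    rates: list[str] = field(default_factory=lambda: list(RATE_INTERVALS))
    input: Optional[dict] = None      # {detections, dialect, frames_map, labels}
    simulate: Optional[dict] = None   # {n_sows, draws, config: {SimConfig fields}}
    window_h: float = 24.0
    step_min: float = 15.0
    initial_window_h: float = 48.0
    nvr: float = 1e-3
    ci_multiplier: float = 6.0

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ValidationError(
                "config must declare exactly one of 'input' and 'simulate'"
            )
        if self.rate not in RATE_INTERVALS:
            raise ConfigurationError(f"unsupported rate {self.rate!r}")
        for r in self.rates:
            if r not in RATE_INTERVALS:
                raise ConfigurationError(f"unsupported rate {r!r} in rates list")

    # -- loading ---------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    # -- derived objects -------------------------------------------------
    def sim_config(self) -> SimConfig:
        overrides = dict((self.simulate or {}).get("config", {}))
        overrides.setdefault("seed", self.seed)
        return SimConfig(**overrides)

    def parameter_draws(self) -> Optional[dict]:
        raw = (self.simulate or {}).get("draws")
        if raw is None:
            return None
        return {k: tuple(v) for k, v in raw.items()}

    def alarm_config(self) -> AlarmConfig:
        return AlarmConfig(
            initial_window=self.initial_window_h * HOUR,
            step=self.step_min * 60.0,
            irw=IRWParams(nvr=self.nvr, ci_multiplier=self.ci_multiplier),
        )

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("log_level", None)
        canonical = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_cohort(config: PipelineConfig) -> list[tuple[object, Optional[FarrowingEvent]]]:
    """Materialise the cohort declared by the config.

    Simulated cohorts come back as observed centroid tracks; file inputs are
    split into per-pen streams (one pen = one sow) and matched to labels by
    sow id.  A stream without a label gets ``event=None`` (alarms still run;
    evaluation skips it with a warning).
    """
    if config.simulate is not None:
        n = int(config.simulate.get("n_sows", 1))
        return list(
            iter_cohort(
                n,
                base_config=config.sim_config(),
                parameter_draws=config.parameter_draws(),
                seed=config.seed,
                as_tracks=True,
            )
        )
    spec = config.input or {}
    frames = read_detection_stream(
        spec["detections"], dialect=spec.get("dialect", "csv"),
        frames_map=spec.get("frames_map"),
    )
    events = {
        e.sow_id: e for e in read_farrowing_labels(spec["labels"])
    } if spec.get("labels") else {}
    by_pen: dict[str, list] = {}
    for f in frames:
        by_pen.setdefault(f.pen_id, []).append(f)
    cohort = []
    for pen_id in sorted(by_pen):
        cohort.append((by_pen[pen_id], events.get(pen_id)))
    return cohort


def write_trend_estimate(estimate, path) -> None:
    """CSV dump of a trend estimate (time, trend, slope, variance, bounds)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "trend", "slope", "trend_var", "ci_lower", "ci_upper"])
        for i in range(len(estimate)):
            writer.writerow(
                [
                    repr(float(estimate.times[i])),
                    repr(float(estimate.trend[i])),
                    repr(float(estimate.slope[i])),
                    repr(float(estimate.trend_var[i])),
                    repr(float(estimate.ci_lower[i])),
                    repr(float(estimate.ci_upper[i])),
                ]
            )


def _sow_id_of(stream, event) -> str:
    if event is not None:
        return event.sow_id
    if hasattr(stream, "sow_id"):
        return stream.sow_id
    return stream[0].pen_id if stream else "unknown"


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full chain at ``config.rate`` and write all artifacts.

    Per-sow failures (e.g. a stream too short for the 48 h initial window)
    are logged and the run continues; such sows appear as missed in the
    evaluation.  Returns the evaluation summary dict.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = load_cohort(config)
    alarm_cfg = config.alarm_config()

    outcomes: list[AlarmOutcome] = []
    pairs: list[tuple[AlarmOutcome, FarrowingEvent]] = []
    for stream, event in cohort:
        sow_id = _sow_id_of(stream, event)
        try:
            smoothed, outcome = run_sow_pipeline(
                stream, sow_id, config.rate, alarm_cfg,
                window=config.window_h * HOUR, step=config.step_min * 60.0,
            )
        except Exception as exc:  # per-sow failure must not kill the cohort run
            logger.warning("sow %s failed: %s", sow_id, exc)
            continue
        write_activity_series(smoothed, out / f"smoothed_{sow_id}.csv")
        est = irw_smooth(smoothed.values, alarm_cfg.irw, times=smoothed.times)
        write_trend_estimate(est, out / f"trend_{sow_id}.csv")
        outcomes.append(outcome)
        logger.info(
            "sow %s: first=%s second=%s", sow_id, outcome.first_stage, outcome.second_stage
        )
        if event is not None:
            pairs.append((outcome, event))
        else:
            logger.warning("sow %s has no farrowing label; excluded from evaluation", sow_id)

    write_alarm_report(outcomes, out / "alarms.csv")
    summary: dict = {"rate": config.rate, "n_sows": len(outcomes)}
    if pairs:
        evaluation = cohort_summary(
            [classify(o, e) for o, e in pairs], rate=config.rate
        )
        summary = evaluation.to_dict()
    with open(out / "evaluation.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "package": "nestwatch",
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return summary


def run_sweep(config: PipelineConfig, out_dir=None) -> dict:
    """Frame-rate sweep over ``config.rates``; writes ``sweep.json``."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = [(s, e) for s, e in load_cohort(config) if e is not None]
    if not cohort:
        raise ValidationError("sweep requires labelled streams")
    evals = frame_rate_sweep(
        cohort, config.rates, config.alarm_config(),
        window=config.window_h * HOUR, step=config.step_min * 60.0,
    )
    result = {rate: ev.to_dict() for rate, ev in evals.items()}
    with open(out / "sweep.json", "w") as fh:
        json.dump(result, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return result
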