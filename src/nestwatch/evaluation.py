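"""Classify alarms against farrowing labels and summarise cohorts.

A first-stage alarm is a *true positive* when it falls in the preferred
window — within 48 h before the onset of farrowing — a *false alarm* when
earlier than 48 h before onset, and *after onset* when at or past onset (an
alarm at exactly the onset counts as after onset: it was not supposed to be
generated after the onset, and the boundary is resolved strictly).  A
second-stage alarm is *valid* when it follows the first stage and is not
later than the end of farrowing.

Cohort summaries report the proportion of sows with alarms in the preferred
windows (all sows in the denominator, missed sows included) and the
median/quartile timing of alarms relative to onset (over sows with the
relevant alarm only; quartiles by linear interpolation between order
statistics).  Because it is ambiguous whether second-stage proportions
should be taken over all sows or only over sows with a first-stage alarm,
both are reported.

:func:`frame_rate_sweep` repeats the whole chain — down-sample, activity,
24 h smoothing, expanding-window alarms, classification — at each requested
frame rate, quantifying how performance degrades as the rate drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .activity import (
    CentroidTrack,
    SmoothedActivitySeries,
    downsample,
    euclidean_activity,
    sliding_mean,
    track_from_frames,
)
from .alarms import AlarmConfig, AlarmOutcome, detect_alarms
from .detections_io import FarrowingEvent
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "PREFERRED_WINDOW",
    "AlarmClassification",
    "CohortEvaluation",
    "classify",
    "cohort_summary",
    "run_sow_pipeline",
    "frame_rate_sweep",
]

HOUR = 3600.0
#: Preferred lead time: first-stage alarms should fall within 48 h before onset.
PREFERRED_WINDOW = 48 * HOUR

FIRST_STATUSES = ("true_positive", "false_alarm", "after_onset", "missed")
SECOND_STATUSES = ("valid", "invalid", "missed")


@dataclass(frozen=True)
class AlarmClassification:
    """Per-sow alarm verdicts; offsets are hours before onset (signed)."""

    sow_id: str
    first_stage_status: str
    second_stage_status: str
    first_offset_h: Optional[float] = None
    second_offset_h: Optional[float] = None


@dataclass
class CohortEvaluation:
    """Cohort-level summary at one frame rate."""

    rate: str
    n_sows: int
    first_counts: dict[str, int]
    second_counts: dict[str, int]
    # proportions over all sows
    first_stage_proportion: float
    second_stage_proportion: float
    # second-stage proportion over sows that got a first-stage alarm
    second_stage_proportion_given_first: float
    first_offset_quartiles_h: Optional[tuple[float, float, float]]   # Q1, median, Q3
    second_offset_quartiles_h: Optional[tuple[float, float, float]]
    classifications: list[AlarmClassification] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "n_sows": self.n_sows,
            "first_counts": dict(self.first_counts),
            "second_counts": dict(self.second_counts),
            "first_stage_proportion": self.first_stage_proportion,
            "second_stage_proportion": self.second_stage_proportion,
            "second_stage_proportion_given_first": self.second_stage_proportion_given_first,
            "first_offset_quartiles_h": self.first_offset_quartiles_h,
            "second_offset_quartiles_h": self.second_offset_quartiles_h,
        }


def classify(outcome: AlarmOutcome, event: FarrowingEvent) -> AlarmClassification:
    """Map one sow's alarm times onto the status taxonomy.

    Classification is total: every (outcome, event) pair yields exactly one
    status per stage.
    """
    if outcome.sow_id != event.sow_id:
        raise ValidationError(
            f"sow_id mismatch: outcome {outcome.sow_id!r} vs event {event.sow_id!r}"
        )
    first_offset = second_offset = None
    t1 = outcome.first_stage
    if t1 is None:
        first_status = "missed"
    else:
        first_offset = (event.onset - t1) / HOUR
        if t1 >= event.onset:
            first_status = "after_onset"
        elif t1 >= event.onset - PREFERRED_WINDOW:
            first_status = "true_positive"
        else:
            first_status = "false_alarm"
    t2 = outcome.second_stage
    if t2 is None:
        second_status = "missed"
    else:
        second_offset = (event.onset - t2) / HOUR
        if t1 is not None and t1 < t2 <= event.end:
            second_status = "valid"
        else:
            second_status = "invalid"
    return AlarmClassification(
        sow_id=outcome.sow_id,
        first_stage_status=first_status,
        second_stage_status=second_status,
        first_offset_h=first_offset,
        second_offset_h=second_offset,
    )


def _quartiles(values: Sequence[float]) -> Optional[tuple[float, float, float]]:
    if len(values) == 0:
        return None
    q1, med, q3 = np.percentile(np.asarray(values, float), [25, 50, 75])
    return (float(q1), float(med), float(q3))


def cohort_summary(
    classifications: Iterable[AlarmClassification], rate: str = "1fps"
) -> CohortEvaluation:
    """Aggregate per-sow classifications into a cohort evaluation row."""
    cls = list(classifications)
    if not cls:
        raise ValidationError("cohort_summary needs at least one classification")
    n = len(cls)
    first_counts = {s: 0 for s in FIRST_STATUSES}
    second_counts = {s: 0 for s in SECOND_STATUSES}
    for c in cls:
        first_counts[c.first_stage_status] += 1
        second_counts[c.second_stage_status] += 1
    n_first = n - first_counts["missed"]
    first_offsets = [c.first_offset_h for c in cls if c.first_offset_h is not None]
    second_offsets = [c.second_offset_h for c in cls if c.second_offset_h is not None]
    return CohortEvaluation(
        rate=rate,
        n_sows=n,
        first_counts=first_counts,
        second_counts=second_counts,
        first_stage_proportion=first_counts["true_positive"] / n,
        second_stage_proportion=second_counts["valid"] / n,
        second_stage_proportion_given_first=(
            second_counts["valid"] / n_first if n_first else 0.0
        ),
        first_offset_quartiles_h=_quartiles(first_offsets),
        second_offset_quartiles_h=_quartiles(second_offsets),
        classifications=cls,
    )


def _as_track(stream, sow_id: str) -> CentroidTrack:
    if isinstance(stream, CentroidTrack):
        return stream
    return track_from_frames(stream, sow_id=sow_id)


def run_sow_pipeline(
    stream,
    sow_id: str,
    rate: str,
    alarm_config: AlarmConfig = AlarmConfig(),
    window: float = 24 * HOUR,
    step: float = 15 * 60.0,
) -> tuple[SmoothedActivitySeries, AlarmOutcome]:
    """Down-sample -> activity -> 24 h smoothing -> alarms, for one sow.

    ``stream`` is a detection-frame list or an already-selected centroid
    track at the source rate.
    """
    track = _as_track(stream, sow_id)
    if track.rate != rate:
        track = downsample(track, rate)
    series = euclidean_activity(track)
    smoothed = sliding_mean(series, window=window, step=step)
    return smoothed, detect_alarms(smoothed, alarm_config)


def frame_rate_sweep(
    cohort: Sequence[tuple[object, FarrowingEvent]],
    rates: Sequence[str],
    alarm_config: AlarmConfig = AlarmConfig(),
    window: float = 24 * HOUR,
    step: float = 15 * 60.0,
) -> dict[str, CohortEvaluation]:
    """Evaluate the full pipeline at each requested frame rate.

    Returns one :class:`CohortEvaluation` per rate, keyed by rate name.
    Sows whose series is too short for the procedure at a given rate are
    classified as missed on both stages.  Deterministic given cohort and
    configuration.
    """
    tracks = [(_as_track(stream, event.sow_id), event) for stream, event in cohort]
    out: dict[str, CohortEvaluation] = {}
    for rate in rates:
        cls = []
        for track, event in tracks:
            try:
                _, outcome = run_sow_pipeline(
                    track, event.sow_id, rate, alarm_config, window=window, step=step
                )
            except InsufficientDataError:
                cls.append(
                    AlarmClassification(event.sow_id, "missed", "missed")
                )
                continue
            cls.append(classify(outcome, event))
        out[rate] = cohort_summary(cls, rate=rate)
    return out


def plot_alarm_offsets(evaluations: dict[str, CohortEvaluation], path) -> None:
    """Box plot of alarm lead times (h before onset) per rate and stage."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rates = list(evaluations)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, which, title in (
        (axes[0], "first_offset_h", "first-stage"),
        (axes[1], "second_offset_h", "second-stage"),
    ):
        data = [
            [getattr(c, which) for c in evaluations[r].classifications
             if getattr(c, which) is not None]
            for r in rates
        ]
        ax.boxplot([d if d else [np.nan] for d in data], tick_labels=rates)
        ax.set_title(f"{title} alarm lead time")
        ax.set_xlabel("frame rate")
    axes[0].set_ylabel("hours before farrowing onset")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_detection_proportions(evaluations: dict[str, CohortEvaluation], path) -> None:
    """Bar chart of the proportion of sows with alarms in the preferred windows."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rates = list(evaluations)
    x = np.arange(len(rates))
    first = [evaluations[r].first_stage_proportion for r in rates]
    second = [evaluations[r].second_stage_proportion for r in rates]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(x - 0.2, first, width=0.4, label="first stage")
    ax.bar(x + 0.2, second, width=0.4, label="second stage")
    ax.set_xticks(x, rates)
    ax.set_ylim(0, 1)
    ax.set_xlabel("frame rate")
    ax.set_ylabel("proportion of sows")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
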