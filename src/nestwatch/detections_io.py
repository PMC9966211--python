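"""Detection-stream and farrowing-label I/O.

The pipeline consumes per-frame sow detections produced by an upstream object
detector (one class, "sow"), together with farrowing-event labels.  This
module defines the corresponding domain types and reads/writes them in two
plain-text dialects:

``csv``
    Long format, one detection per row, with an explicit empty-frame
    sentinel (a row whose box columns are blank).  A frame with no
    detections is a record, not an omission.

``coco_results_json``
    The COCO detection-results convention emitted by MMDetection-style
    inference: a JSON list of ``{image_id, bbox [x, y, w, h], score,
    category_id}``, plus a sidecar JSON mapping ``image_id`` to
    ``{pen_id, time}`` so frame indices can be placed on the time axis.

Timestamps are seconds (float) from stream start; calendar anchoring is
metadata kept outside the pipeline, since every quantity of interest is an
offset relative to farrowing onset.  Boxes use the COCO convention:
top-left corner plus width/height, x rightward, y downward, continuous
pixel coordinates.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from .errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .activity import ActivitySeries, SmoothedActivitySeries
    from .alarms import AlarmOutcome

__all__ = [
    "BoundingBox",
    "Detection",
    "DetectionFrame",
    "FarrowingEvent",
    "read_detection_stream",
    "write_detection_stream",
    "read_farrowing_labels",
    "write_farrowing_labels",
    "write_activity_series",
    "read_activity_series",
    "write_alarm_report",
    "read_alarm_report",
]

# Field order of the long-format CSV dialect.  Empty-frame sentinel rows
# leave every column after `time` blank.
_CSV_COLUMNS = ("pen_id", "time", "x", "y", "w", "h", "score", "label")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: top-left corner ``(x, y)``, width ``w``, height ``h``, in pixels."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(
                f"bounding box must have positive extent, got w={self.w}, h={self.h}"
            )

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x + self.w / 2.0, self.y + self.h / 2.0)

    @property
    def area(self) -> float:
        return self.w * self.h


@dataclass(frozen=True)
class Detection:
    """One detector hit: a box, its confidence score, and the object class."""

    box: BoundingBox
    score: float
    label: str = "sow"

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValidationError(f"score must be in [0, 1], got {self.score}")


@dataclass
class DetectionFrame:
    """All candidate sow boxes observed at one timestamp in one pen.

    ``detections`` may be empty: an empty frame means the detector ran and
    found nothing, which downstream stages must see (it creates a gap in the
    centroid track rather than silently shortening it).
    """

    pen_id: str
    time: float
    detections: list[Detection] = field(default_factory=list)


@dataclass(frozen=True)
class FarrowingEvent:
    """Farrowing label for one sow.

    ``onset`` is the moment the first piglet's body drops to the floor;
    ``end`` is the birth of the last piglet.  Both are seconds on the same
    clock as the detection stream.
    """

    sow_id: str
    onset: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.onset:
            raise ValidationError(
                f"farrowing end ({self.end}) before onset ({self.onset}) for sow {self.sow_id}"
            )


def _check_monotone(frames: Sequence[DetectionFrame], source: str) -> None:
    for i in range(1, len(frames)):
        if frames[i].time <= frames[i - 1].time:
            raise ValidationError(
                f"{source}: timestamps not strictly increasing at entry {i} "
                f"({frames[i - 1].time} -> {frames[i].time})"
            )


def _parse_float(value: str, line: int, column: str) -> float:
    try:
        out = float(value)
    except ValueError:
        raise ParseError(f"line {line}: column {column!r} is not a number: {value!r}") from None
    if not math.isfinite(out):
        raise ParseError(f"line {line}: column {column!r} is not finite: {value!r}")
    return out


def read_detection_stream(
    path,
    dialect: str = "csv",
    frames_map=None,
) -> list[DetectionFrame]:
    """Read a detection stream into time-sorted :class:`DetectionFrame` records.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"csv"`` (long format with empty-frame sentinel rows) or
        ``"coco_results_json"``.
    frames_map
        For the COCO dialect only: path to (or dict of) the sidecar mapping
        ``image_id -> {"pen_id": ..., "time": ...}``.  Image ids present in
        the sidecar but absent from the results list become empty frames.

    Raises
    ------
    ParseError
        Malformed record; the message names the line/entry.
    ValidationError
        Timestamps not strictly increasing within a pen stream.
    """
    if dialect == "csv":
        frames = _read_csv_stream(path)
    elif dialect == "coco_results_json":
        frames = _read_coco_stream(path, frames_map)
    else:
        raise ParseError(f"unknown detection dialect: {dialect!r}")
    frames.sort(key=lambda f: (f.pen_id, f.time))
    for pen in {f.pen_id for f in frames}:
        _check_monotone([f for f in frames if f.pen_id == pen], str(path))
    return frames


def _read_csv_stream(path) -> list[DetectionFrame]:
    by_key: dict[tuple[str, float], DetectionFrame] = {}
    order: list[tuple[str, float]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _CSV_COLUMNS:
            raise ParseError(
                f"{path}: expected header {','.join(_CSV_COLUMNS)}, got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            pen_id = row["pen_id"]
            time = _parse_float(row["time"], i, "time")
            key = (pen_id, time)
            if key not in by_key:
                by_key[key] = DetectionFrame(pen_id=pen_id, time=time)
                order.append(key)
            if (row["x"] or "") == "":
                # empty-frame sentinel: remaining columns must be blank too
                if any((row[c] or "") != "" for c in ("y", "w", "h", "score")):
                    raise ParseError(f"line {i}: partial empty-frame sentinel")
                continue
            box = BoundingBox(
                x=_parse_float(row["x"], i, "x"),
                y=_parse_float(row["y"], i, "y"),
                w=_parse_float(row["w"], i, "w"),
                h=_parse_float(row["h"], i, "h"),
            )
            score = _parse_float(row["score"], i, "score")
            try:
                det = Detection(box=box, score=score, label=row["label"] or "sow")
            except ValidationError as exc:
                raise ParseError(f"line {i}: {exc}") from None
            by_key[key].detections.append(det)
    return [by_key[k] for k in order]


def _read_coco_stream(path, frames_map) -> list[DetectionFrame]:
    if frames_map is None:
        raise ParseError("coco_results_json dialect requires a frames_map sidecar")
    if isinstance(frames_map, (str, bytes)) or hasattr(frames_map, "__fspath__"):
        with open(frames_map) as fh:
            frames_map = json.load(fh)
    with open(path) as fh:
        try:
            results = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from None
    if not isinstance(results, list):
        raise ParseError(f"{path}: COCO results must be a JSON list")

    frames: dict[str, DetectionFrame] = {}
    for image_id, meta in frames_map.items():
        frames[str(image_id)] = DetectionFrame(
            pen_id=str(meta["pen_id"]), time=float(meta["time"])
        )
    for i, rec in enumerate(results):
        try:
            image_id = str(rec["image_id"])
            bx, by, bw, bh = rec["bbox"]
            score = float(rec["score"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"entry {i}: malformed COCO result record: {exc}") from None
        if image_id not in frames:
            raise ParseError(f"entry {i}: image_id {image_id!r} missing from frames_map")
        try:
            det = Detection(
                box=BoundingBox(float(bx), float(by), float(bw), float(bh)),
                score=score,
                label=str(rec.get("category_id", "sow")),
            )
        except ValidationError as exc:
            raise ParseError(f"entry {i}: {exc}") from None
        frames[image_id].detections.append(det)
    return list(frames.values())


def write_detection_stream(frames: Iterable[DetectionFrame], path, dialect: str = "csv") -> None:
    """Write frames in the given dialect; inverse of :func:`read_detection_stream`.

    The COCO dialect writes the sidecar next to ``path`` with suffix
    ``.frames.json``.
    """
    frames = list(frames)
    if dialect == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for f in frames:
                if not f.detections:
                    writer.writerow([f.pen_id, repr(float(f.time)), "", "", "", "", "", ""])
                for d in f.detections:
                    writer.writerow(
                        [
                            f.pen_id,
                            repr(float(f.time)),
                            repr(float(d.box.x)),
                            repr(float(d.box.y)),
                            repr(float(d.box.w)),
                            repr(float(d.box.h)),
                            repr(float(d.score)),
                            d.label,
                        ]
                    )
    elif dialect == "coco_results_json":
        results = []
        sidecar = {}
        for i, f in enumerate(frames):
            image_id = str(i)
            sidecar[image_id] = {"pen_id": f.pen_id, "time": f.time}
            for d in f.detections:
                results.append(
                    {
                        "image_id": image_id,
                        "bbox": [d.box.x, d.box.y, d.box.w, d.box.h],
                        "score": d.score,
                        "category_id": d.label,
                    }
                )
        with open(path, "w") as fh:
            json.dump(results, fh)
        with open(f"{path}.frames.json", "w") as fh:
            json.dump(sidecar, fh)
    else:
        raise ParseError(f"unknown detection dialect: {dialect!r}")


def read_farrowing_labels(path) -> list[FarrowingEvent]:
    """Read a label CSV with columns ``sow_id, onset, end`` (seconds).

    One event per sow; duplicate sow ids or ``end < onset`` raise
    :class:`~nestwatch.errors.ValidationError`.
    """
    events: list[FarrowingEvent] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sow_id", "onset", "end"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: expected columns sow_id, onset, end")
        for i, row in enumerate(reader, start=2):
            sow_id = row["sow_id"]
            if sow_id in seen:
                raise ValidationError(f"line {i}: duplicate sow_id {sow_id!r}")
            seen.add(sow_id)
            events.append(
                FarrowingEvent(
                    sow_id=sow_id,
                    onset=_parse_float(row["onset"], i, "onset"),
                    end=_parse_float(row["end"], i, "end"),
                )
            )
    return events


def write_farrowing_labels(events: Iterable[FarrowingEvent], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sow_id", "onset", "end"])
        for e in events:
            writer.writerow([e.sow_id, repr(float(e.onset)), repr(float(e.end))])


def write_activity_series(series, path) -> None:
    """Write an :class:`ActivitySeries` or :class:`SmoothedActivitySeries` as CSV.

    Columns: ``sow_id, rate, time, value[, gap]``.  Values are written with
    full ``repr`` precision so a round-trip is lossless.
    """
    gaps = getattr(series, "gap_flags", None)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["sow_id", "rate", "time", "value"]
        if gaps is not None:
            header.append("gap")
        writer.writerow(header)
        for i, (t, v) in enumerate(zip(series.times, series.values)):
            row = [series.sow_id, series.rate, repr(float(t)), repr(float(v))]
            if gaps is not None:
                row.append(str(int(gaps[i])))
            writer.writerow(row)


def read_activity_series(path):
    """Read a CSV written by :func:`write_activity_series`.

    Returns an :class:`~nestwatch.activity.ActivitySeries` if the file has a
    ``gap`` column, else a :class:`~nestwatch.activity.SmoothedActivitySeries`.
    An empty (header-only) file yields an empty series with ``sow_id=None``.
    """
    import numpy as np

    from .activity import ActivitySeries, SmoothedActivitySeries

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        has_gap = reader.fieldnames is not None and "gap" in reader.fieldnames
        sow_id = None
        rate = None
        times: list[float] = []
        values: list[float] = []
        gaps: list[bool] = []
        for i, row in enumerate(reader, start=2):
            sow_id = row["sow_id"]
            rate = row["rate"]
            times.append(_parse_float(row["time"], i, "time"))
            values.append(_parse_float(row["value"], i, "value"))
            if has_gap:
                gaps.append(bool(int(row["gap"])))
    t = np.asarray(times)
    v = np.asarray(values)
    if has_gap:
        return ActivitySeries(sow_id=sow_id, rate=rate, times=t, values=v,
                              gap_flags=np.asarray(gaps, dtype=bool))
    return SmoothedActivitySeries(sow_id=sow_id, rate=rate, times=t, values=v)


def write_alarm_report(outcomes: Iterable["AlarmOutcome"], path) -> None:
    """Write one row per sow: ``sow_id, first_stage, second_stage, status``.

    A sow with no alarms gets an explicit ``none`` marker, never a missing
    row, so the report is total over the cohort.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sow_id", "first_stage", "second_stage", "status"])
        for o in outcomes:
            first = "none" if o.first_stage is None else repr(float(o.first_stage))
            second = "none" if o.second_stage is None else repr(float(o.second_stage))
            if o.first_stage is None:
                status = "no_alarm"
            elif o.second_stage is None:
                status = "first_only"
            else:
                status = "both_stages"
            writer.writerow([o.sow_id, first, second, status])


def read_alarm_report(path) -> list["AlarmOutcome"]:
    """Read an alarm report back into (trace-less) alarm outcomes."""
    from .alarms import AlarmOutcome, AlarmTrace
    import numpy as np

    empty = lambda: AlarmTrace(*(np.empty(0) for _ in range(5)))  # noqa: E731
    outcomes = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sow_id" not in reader.fieldnames:
            raise ParseError(f"{path}: not an alarm report")
        for i, row in enumerate(reader, start=2):
            first = None if row["first_stage"] == "none" else _parse_float(
                row["first_stage"], i, "first_stage")
            second = None if row["second_stage"] == "none" else _parse_float(
                row["second_stage"], i, "second_stage")
            outcomes.append(
                AlarmOutcome(sow_id=row["sow_id"], first_stage=first,
                             second_stage=second, trace=empty())
            )
    return outcomes
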