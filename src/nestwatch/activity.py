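"""Sow activity level from centroid tracks.

The activity variable that drives farrowing prediction is the Euclidean
distance between consecutive bounding-box centroids.  This module turns a
detection stream into that variable:

1. :func:`select_centroid` — pick one centroid per frame (highest score,
   ties broken by larger box area, then first listed);
2. :func:`downsample` — resample the 1 fps centroid track onto one of the
   supported lower rates (40/20/5/1 fpm, 12/4 fph);
3. :func:`euclidean_activity` — per-interval step length in pixels;
4. :func:`sliding_mean` — trailing 24 h mean on a 15 min grid, which
   averages out the diurnal rhythm and yields the smoothed input variable
   for trend estimation.  The first 12 h of the input are dropped as
   warm-up.

Distances are pixels per sampling interval (not normalised to px/s): the
series is rate-dependent by design, and cross-rate comparability is handled
by the scale-free confidence-interval alarm rule plus the per-sow
:func:`normalize` used for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .detections_io import DetectionFrame
from .errors import ConfigurationError, InsufficientDataError, ValidationError

__all__ = [
    "RATE_INTERVALS",
    "rate_interval",
    "CentroidTrack",
    "ActivitySeries",
    "SmoothedActivitySeries",
    "select_centroid",
    "track_from_frames",
    "downsample",
    "euclidean_activity",
    "sliding_mean",
    "normalize",
]

#: Supported sampling rates -> frame interval in seconds.
RATE_INTERVALS: dict[str, float] = {
    "1fps": 1.0,
    "40fpm": 1.5,
    "20fpm": 3.0,
    "5fpm": 12.0,
    "1fpm": 60.0,
    "12fph": 300.0,
    "4fph": 900.0,
}

HOUR = 3600.0
DEFAULT_WINDOW = 24 * HOUR     # sliding-mean window
DEFAULT_STEP = 15 * 60.0       # sliding-mean step / smoothed grid spacing
WARMUP = 12 * HOUR             # smoothed series starts this long after the input


def rate_interval(rate: str) -> float:
    """Seconds between frames at the named rate; unknown rate -> ConfigurationError."""
    try:
        return RATE_INTERVALS[rate]
    except KeyError:
        raise ConfigurationError(
            f"unsupported rate {rate!r}; supported: {sorted(RATE_INTERVALS)}"
        ) from None


@dataclass
class CentroidTrack:
    """Per-sow time series of selected centroids on a nominal uniform grid.

    ``times`` are strictly increasing and lie on the declared rate's grid;
    grid points where the frame was empty are simply absent.
    """

    sow_id: str
    rate: str
    times: np.ndarray            # seconds, shape (n,)
    xy: np.ndarray               # pixels, shape (n, 2)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if len(self.times) != len(self.xy):
            raise ValidationError("times and xy length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("track times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ActivitySeries:
    """Euclidean step lengths: one sample per consecutive centroid pair.

    ``gap_flags[i]`` marks a distance computed across missing frames (the
    time gap exceeded the nominal interval), so downstream users can tell
    bridged samples from regular ones.
    """

    sow_id: str
    rate: str
    times: np.ndarray
    values: np.ndarray
    gap_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.gap_flags is None:
            self.gap_flags = np.zeros(len(self.times), dtype=bool)
        self.gap_flags = np.asarray(self.gap_flags, dtype=bool)
        if np.any(self.values < 0):
            raise ValidationError("activity distances must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SmoothedActivitySeries:
    """Trailing 24 h mean of activity on a 15 min grid — the trend-model input."""

    sow_id: str
    rate: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.times)


def select_centroid(frame: DetectionFrame) -> Optional[tuple[float, float]]:
    """Centroid of the most plausible sow detection in a frame, or None if empty.

    Highest confidence wins; exact score ties go to the larger box area,
    remaining ties to the first-listed detection.
    """
    best = None
    best_key = None
    for det in frame.detections:
        key = (det.score, det.box.area)
        if best_key is None or key > best_key:
            best, best_key = det, key
    return None if best is None else best.box.centroid


def track_from_frames(
    frames: list[DetectionFrame], sow_id: str, rate: str = "1fps"
) -> CentroidTrack:
    """Build a centroid track from a detection stream (one pen = one sow)."""
    times = []
    xy = []
    for f in frames:
        c = select_centroid(f)
        if c is not None:
            times.append(f.time)
            xy.append(c)
    return CentroidTrack(
        sow_id=sow_id,
        rate=rate,
        times=np.asarray(times, dtype=float),
        xy=np.asarray(xy, dtype=float).reshape(-1, 2),
    )


def downsample(track: CentroidTrack, target_rate: str) -> CentroidTrack:
    """Resample a track onto the uniform grid of ``target_rate``.

    Each target grid point takes the nearest available source point within
    half a target interval; grid points with no source point in range are
    absent from the result.  Downsampling to the track's own rate is the
    identity.
    """
    src_dt = rate_interval(track.rate)
    dt = rate_interval(target_rate)
    if dt < src_dt:
        raise ConfigurationError(
            f"target rate {target_rate!r} is faster than source rate {track.rate!r}"
        )
    if len(track) == 0:
        return CentroidTrack(track.sow_id, target_rate, np.empty(0), np.empty((0, 2)))
    t0 = track.times[0]
    grid = t0 + dt * np.arange(int(np.floor((track.times[-1] - t0) / dt)) + 1)
    # nearest source sample to each grid point
    idx = np.searchsorted(track.times, grid)
    idx_left = np.clip(idx - 1, 0, len(track) - 1)
    idx_right = np.clip(idx, 0, len(track) - 1)
    d_left = np.abs(track.times[idx_left] - grid)
    d_right = np.abs(track.times[idx_right] - grid)
    nearest = np.where(d_right < d_left, idx_right, idx_left)
    dist = np.abs(track.times[nearest] - grid)
    keep = dist <= dt / 2.0
    return CentroidTrack(
        sow_id=track.sow_id,
        rate=target_rate,
        times=grid[keep],
        xy=track.xy[nearest[keep]],
    )


def euclidean_activity(track: CentroidTrack) -> ActivitySeries:
    """Euclidean distance between consecutive available centroids.

    The sample for the pair ``(t_i, t_{i+1})`` is stamped at ``t_{i+1}``.
    Gaps (missing frames between the pair) are bridged — the distance is
    still computed — and flagged.  A track with fewer than two points yields
    an empty series with a warning rather than an exception.
    """
    if len(track) < 2:
        warnings.warn(
            f"track {track.sow_id!r} has {len(track)} point(s); activity series is empty",
            stacklevel=2,
        )
        return ActivitySeries(track.sow_id, track.rate, np.empty(0), np.empty(0))
    steps = np.diff(track.xy, axis=0)
    d = np.hypot(steps[:, 0], steps[:, 1])
    dt = np.diff(track.times)
    nominal = rate_interval(track.rate)
    gaps = dt > nominal * 1.5
    return ActivitySeries(track.sow_id, track.rate, track.times[1:], d, gaps)


def sliding_mean(
    series: ActivitySeries,
    window: float = DEFAULT_WINDOW,
    step: float = DEFAULT_STEP,
    warmup: float = WARMUP,
) -> SmoothedActivitySeries:
    """Trailing mean over ``window`` seconds, evaluated every ``step`` seconds.

    The output grid runs from ``warmup`` (default 12 h) after the first
    sample to the last sample; each value is the mean of the samples in the
    half-open trailing window ``(t - window, t]``.  Before a full window has
    elapsed the partial window (at least ``warmup`` long) is used.  Windows
    use available samples only — no imputation across gaps.
    """
    if len(series) == 0 or series.times[-1] - series.times[0] < warmup:
        raise InsufficientDataError(
            f"insufficient history: series spans "
            f"{0.0 if len(series) == 0 else series.times[-1] - series.times[0]:.0f} s, "
            f"need >= {warmup:.0f} s"
        )
    t0 = series.times[0]
    n_steps = int(np.floor((series.times[-1] - t0 - warmup) / step))
    grid = t0 + warmup + step * np.arange(n_steps + 1)
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    hi = np.searchsorted(series.times, grid, side="right")
    lo = np.searchsorted(series.times, grid - window, side="right")
    counts = hi - lo
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, (csum[hi] - csum[lo]) / np.maximum(counts, 1), 0.0)
    return SmoothedActivitySeries(series.sow_id, series.rate, grid, vals)


def normalize(series: SmoothedActivitySeries) -> SmoothedActivitySeries:
    """Per-sow min-max scaling to [0, 1]; a constant series maps to all zeros.

    Used for cross-rate presentation only — the alarm path consumes the
    unnormalised smoothed series.
    """
    if len(series) == 0:
        raise InsufficientDataError("cannot normalize an empty series")
    lo = float(np.min(series.values))
    hi = float(np.max(series.values))
    if hi > lo:
        vals = (series.values - lo) / (hi - lo)
    else:
        vals = np.zeros_like(series.values)
    return SmoothedActivitySeries(series.sow_id, series.rate, series.times.copy(), vals)
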