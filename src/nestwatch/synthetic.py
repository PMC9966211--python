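"""Synthetic sow centroid trajectories and noisy detection streams.

Every downstream stage of the pipeline is exercised on synthetic data with
the statistical structure the analysis assumes about real farrowing pens:

* a sow moving inside a rectangular pen, observed at a uniform frame rate
  (1 fps by default) over roughly five days before the expected farrowing;
* a diurnal rhythm in activity (24 h sinusoidal modulation of step length);
* persistent behavioural variability — resting, feeding and standing bouts
  make real activity wander smoothly on a scale of hours; modelled as a
  mean-one log-Ornstein-Uhlenbeck modulation of the step length.  Without
  it the smoothed activity series would contain nothing but sampling
  noise, a degenerate null no adaptive alarm band can be judged against;
* a nest-building surge: activity rises in the hours before farrowing
  onset, peaks a few hours before onset, and declines again as farrowing
  approaches, staying low while farrowing is in progress;
* detector imperfections: centroid jitter, missed frames, and "decoy"
  episodes — intervals during which the sow goes undetected and a static
  false detection at a fixed pen coordinate stands in for her (a part of
  the pen mistaken for a sow while the real animal is occluded or merged
  with the background).  Each episode yanks the selected centroid across
  the pen and back, producing a pair of pen-scale distance outliers whose
  damage to the 24 h window mean grows as the frame rate drops — few
  samples share the window at low rates — which is what degrades
  farrowing prediction at low frame rates.

Kinematics are deliberately minimal: step directions uniform on the
circle, step magnitudes exponential with mean given by
:func:`activity_profile`, positions reflected at the pen walls.  The
generator makes no claim of matching real effect sizes; it provides a
controllable surge against a controllable noise floor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .activity import CentroidTrack, rate_interval
from .detections_io import BoundingBox, Detection, DetectionFrame, FarrowingEvent
from .errors import ValidationError

__all__ = [
    "SimConfig",
    "activity_profile",
    "simulate_trajectory",
    "inject_detection_noise",
    "simulate_observed_track",
    "simulate_sow",
    "simulate_cohort",
    "iter_cohort",
    "DEFAULT_PARAMETER_DRAWS",
]

HOUR = 3600.0

#: Cohort-level heterogeneity: nest-building start varies between sows.
DEFAULT_PARAMETER_DRAWS: dict[str, tuple] = {
    "surge_start_offset_h": ("uniform", 8.0, 20.0),
}

#: Low-noise study conditions: reduced bout variability and detector noise,
#: no decoy episodes.  Used for parameter-recovery experiments where the
#: question is whether the alarm machinery recovers a known surge, not how
#: it copes with detector failure modes.
LOW_NOISE_OVERRIDES: dict[str, float] = {
    "behavioral_sd": 0.1,
    "jitter_sd": 0.5,
    "miss_rate": 0.01,
    "false_rate": 0.0,
}

# Confidence-score ranges for genuine and decoy detections.
_TRUE_SCORE_RANGE = (0.70, 0.98)
_DECOY_SCORE_RANGE = (0.30, 0.74)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic sow observation period.

    Times are hours from the start of recording; the farrowing onset sits
    near the end of the period, as in pens stocked about five days before
    the expected farrowing date.
    """

    pen_width: float = 800.0          # px
    pen_height: float = 600.0         # px
    duration_h: float = 144.0         # ~5 days of recording
    farrowing_onset_h: float = 120.0
    farrowing_duration_h: float = 4.0
    source_rate: str = "1fps"
    baseline_step: float = 3.0        # px/frame mean step length
    diurnal_amplitude: float = 0.3    # fraction of baseline, in [0, 1)
    diurnal_period_h: float = 24.0
    diurnal_phase: float = 0.0        # radians
    surge_start_offset_h: float = 16.0  # surge begins this long before onset
    surge_peak_offset_h: float = 4.0    # peak "a few h" before onset
    surge_gain: float = 4.0             # multiplicative peak factor
    post_peak_floor: float = 0.5        # fraction of baseline during farrowing
    behavioral_sd: float = 0.25         # log-scale SD of slow activity bouts
    behavioral_tau_h: float = 3.0       # correlation time of the bout process
    jitter_sd: float = 1.0              # px detection jitter
    miss_rate: float = 0.02
    false_rate: float = 0.01            # stationary fraction of time in decoy episodes
    decoy_duration_s: float = 300.0     # mean decoy-episode length
    decoy_position: tuple[float, float] = (40.0, 40.0)
    box_size: tuple[float, float] = (120.0, 60.0)       # sow bounding box w, h
    decoy_box_size: tuple[float, float] = (70.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.surge_start_offset_h > self.surge_peak_offset_h >= 0):
            raise ValidationError(
                "need surge_start_offset_h > surge_peak_offset_h >= 0, got "
                f"{self.surge_start_offset_h}, {self.surge_peak_offset_h}"
            )
        if not (0 <= self.miss_rate <= 1 and 0 <= self.false_rate <= 1):
            raise ValidationError("miss_rate and false_rate must be in [0, 1]")
        if not (0 <= self.diurnal_amplitude < 1):
            raise ValidationError("diurnal_amplitude must be in [0, 1)")
        if self.surge_gain < 1:
            raise ValidationError("surge_gain must be >= 1")
        if self.duration_h <= 0 or self.pen_width <= 0 or self.pen_height <= 0:
            raise ValidationError("duration and pen dimensions must be positive")

    @property
    def onset_s(self) -> float:
        return self.farrowing_onset_h * HOUR

    @property
    def end_s(self) -> float:
        return (self.farrowing_onset_h + self.farrowing_duration_h) * HOUR


def _surge_factor(config: SimConfig, t_h: np.ndarray) -> np.ndarray:
    """Piecewise-linear nest-building surge: 1 -> gain -> floor -> 1.

    Rises from 1 at (onset - surge_start_offset) to surge_gain at
    (onset - surge_peak_offset), declines to post_peak_floor at onset,
    holds the floor until the end of farrowing, then returns to 1.
    """
    onset = config.farrowing_onset_h
    t_rise = onset - config.surge_start_offset_h
    t_peak = onset - config.surge_peak_offset_h
    t_end = onset + config.farrowing_duration_h
    g = config.surge_gain
    floor = config.post_peak_floor
    out = np.ones_like(t_h)
    rising = (t_h >= t_rise) & (t_h < t_peak)
    out = np.where(rising, 1.0 + (g - 1.0) * (t_h - t_rise) / (t_peak - t_rise), out)
    falling = (t_h >= t_peak) & (t_h < onset)
    if onset > t_peak:
        out = np.where(falling, g + (floor - g) * (t_h - t_peak) / (onset - t_peak), out)
    else:  # peak at onset
        out = np.where(t_h == t_peak, g, out)
    out = np.where((t_h >= onset) & (t_h <= t_end), floor, out)
    return out


def activity_profile(config: SimConfig, t_h):
    """Expected step length (px/frame) at time ``t_h`` hours from start.

    ``baseline_step * (1 + A sin(2 pi t / period + phase)) * surge(t)``;
    deterministic given the config.  ``t_h`` may be a scalar or array and
    must lie in ``[0, duration_h]``.
    """
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0) or np.any(t > config.duration_h):
        raise ValidationError(
            f"profile time outside [0, {config.duration_h}] h"
        )
    diurnal = 1.0 + config.diurnal_amplitude * np.sin(
        2 * np.pi * t / config.diurnal_period_h + config.diurnal_phase
    )
    out = config.baseline_step * diurnal * _surge_factor(config, t)
    return float(out) if np.isscalar(t_h) else out


def _reflect(a: np.ndarray, width: float) -> np.ndarray:
    """Fold an unconstrained coordinate into [0, width] (reflecting walls)."""
    m = np.mod(a, 2.0 * width)
    return width - np.abs(m - width)


def _rngs(config: SimConfig) -> tuple[np.random.Generator, ...]:
    """Independent trajectory / noise / behaviour streams from the config seed."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _behavior_factor(config: SimConfig, n: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-one multiplicative bout process: exp of a stationary OU path.

    AR(1) on the frame grid with correlation time ``behavioral_tau_h``;
    the ``exp(b - sd^2/2)`` transform keeps the expected step length equal
    to the activity profile.
    """
    sd = config.behavioral_sd
    if sd <= 0:
        return np.ones(n)
    from scipy.signal import lfilter

    phi = float(np.exp(-dt / (config.behavioral_tau_h * HOUR)))
    eps = rng.normal(0.0, sd, n)
    b0 = rng.normal(0.0, sd)
    innov = eps * np.sqrt(1.0 - phi**2)
    innov[0] = 0.0
    b, _ = lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * b0]))
    return np.exp(b - sd**2 / 2.0)


def simulate_trajectory(config: SimConfig, sow_id: str = "sow") -> CentroidTrack:
    """Simulate the true centroid track on the source-rate grid.

    Per-frame displacement: direction uniform on the circle, magnitude
    exponential with mean :func:`activity_profile` at the frame time;
    positions reflected at the pen walls.  Identical seed, identical track.
    """
    dt = rate_interval(config.source_rate)
    n = int(np.floor(config.duration_h * HOUR / dt)) + 1
    times = dt * np.arange(n)
    rng, _, rng_beh = _rngs(config)
    theta = rng.uniform(0.0, 2 * np.pi, n - 1)
    means = activity_profile(config, times[1:] / HOUR)
    means = means * _behavior_factor(config, n - 1, dt, rng_beh)
    mags = rng.exponential(1.0, n - 1) * means
    steps = np.column_stack([mags * np.cos(theta), mags * np.sin(theta)])
    start = np.array([config.pen_width / 2.0, config.pen_height / 2.0])
    raw = start + np.concatenate([[(0.0, 0.0)], np.cumsum(steps, axis=0)])
    xy = np.column_stack(
        [_reflect(raw[:, 0], config.pen_width), _reflect(raw[:, 1], config.pen_height)]
    )
    return CentroidTrack(sow_id=sow_id, rate=config.source_rate, times=times, xy=xy)


def _decoy_episodes(n: int, dt: float, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean per-frame mask of decoy (detector-confusion) episodes.

    Alternating exponential off/on intervals; the on-fraction is
    ``false_rate`` and the mean on-length ``decoy_duration_s``.
    """
    mask = np.zeros(n, dtype=bool)
    f = config.false_rate
    if f <= 0 or config.decoy_duration_s <= 0:
        return mask
    if f >= 1:
        return ~mask
    on_mean = config.decoy_duration_s
    off_mean = on_mean * (1.0 - f) / f
    t, on = 0.0, False
    total = n * dt
    while t < total:
        length = rng.exponential(on_mean if on else off_mean)
        if on:
            i0 = int(np.ceil(t / dt))
            i1 = min(int(np.floor((t + length) / dt)) + 1, n)
            if i0 < i1:
                mask[i0:i1] = True
        t += length
        on = not on
    return mask


def _sample_noise(n: int, dt: float, config: SimConfig, rng: np.random.Generator) -> dict:
    """All detector-noise draws for n frames, in a fixed order."""
    return {
        "decoy": _decoy_episodes(n, dt, config, rng),
        "miss": rng.random(n) < config.miss_rate,
        "jitter": rng.normal(0.0, config.jitter_sd, (n, 2)) if config.jitter_sd > 0
        else np.zeros((n, 2)),
        "true_score": rng.uniform(*_TRUE_SCORE_RANGE, n),
        "decoy_score": rng.uniform(*_DECOY_SCORE_RANGE, n),
    }


def inject_detection_noise(track: CentroidTrack, config: SimConfig) -> list[DetectionFrame]:
    """Turn a true track into a noisy detection stream.

    During a decoy episode (stationary time fraction ``false_rate``, mean
    length ``decoy_duration_s``) the sow goes undetected and only the
    static decoy at ``decoy_position`` is reported, with a low confidence
    score.  Outside episodes the sow is missed independently with
    probability ``miss_rate`` (empty frame), otherwise detected with
    isotropic centroid jitter and a high score.  Seeded from the config
    (noise stream independent of the trajectory stream).
    """
    _, rng, _ = _rngs(config)
    n = len(track)
    dt = rate_interval(config.source_rate)
    noise = _sample_noise(n, dt, config, rng)
    bw, bh = config.box_size
    dw, dh = config.decoy_box_size
    dx, dy = config.decoy_position
    decoy_box = BoundingBox(x=dx - dw / 2, y=dy - dh / 2, w=dw, h=dh)
    frames: list[DetectionFrame] = []
    for i in range(n):
        frame = DetectionFrame(pen_id=track.sow_id, time=float(track.times[i]))
        if noise["decoy"][i]:
            frame.detections.append(
                Detection(box=decoy_box, score=float(noise["decoy_score"][i]))
            )
        elif not noise["miss"][i]:
            cx = track.xy[i, 0] + noise["jitter"][i, 0]
            cy = track.xy[i, 1] + noise["jitter"][i, 1]
            frame.detections.append(
                Detection(
                    box=BoundingBox(x=cx - bw / 2, y=cy - bh / 2, w=bw, h=bh),
                    score=float(noise["true_score"][i]),
                )
            )
        frames.append(frame)
    return frames


def simulate_observed_track(config: SimConfig, sow_id: str = "sow") -> CentroidTrack:
    """Trajectory + detector noise + centroid selection, fully vectorised.

    Produces exactly the track that ``track_from_frames(inject_detection_noise(
    simulate_trajectory(config)))`` would produce — same random streams, same
    highest-score selection — without materialising per-frame objects, so
    cohort-scale streams at 1 fps stay cheap.
    """
    track = simulate_trajectory(config, sow_id)
    _, rng, _ = _rngs(config)
    dt = rate_interval(config.source_rate)
    noise = _sample_noise(len(track), dt, config, rng)
    visible = noise["decoy"] | ~noise["miss"]
    obs = track.xy + noise["jitter"]
    obs = np.where(noise["decoy"][:, None], np.asarray(config.decoy_position, float), obs)
    return CentroidTrack(
        sow_id=sow_id,
        rate=config.source_rate,
        times=track.times[visible],
        xy=obs[visible],
    )


def simulate_sow(
    config: SimConfig, sow_id: str = "sow", as_track: bool = False
) -> tuple[object, FarrowingEvent]:
    """One sow: detection stream (or observed track) plus its farrowing label.

    The label onset is exactly the onset used to position the surge — the
    generator leaks no unlabeled structure.
    """
    event = FarrowingEvent(sow_id=sow_id, onset=config.onset_s, end=config.end_s)
    if as_track:
        return simulate_observed_track(config, sow_id), event
    track = simulate_trajectory(config, sow_id)
    return inject_detection_noise(track, config), event


def _member_config(
    base: SimConfig,
    index: int,
    cohort_seed: int,
    parameter_draws: Optional[dict],
) -> SimConfig:
    """Per-sow config: independent seed stream and per-sow parameter draws."""
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index,))
    rng = np.random.default_rng(ss)
    updates: dict = {}
    for fname, spec in sorted((parameter_draws or {}).items()):
        kind = spec[0]
        if kind == "uniform":
            updates[fname] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "normal":
            updates[fname] = float(rng.normal(spec[1], spec[2]))
        elif kind == "constant":
            updates[fname] = spec[1]
        else:
            raise ValidationError(f"unknown draw kind {kind!r} for {fname!r}")
    updates["seed"] = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
    return dataclasses.replace(base, **updates)


def iter_cohort(
    n: int,
    base_config: SimConfig = SimConfig(),
    parameter_draws: Optional[dict] = None,
    seed: int = 0,
    as_tracks: bool = False,
) -> Iterator[tuple[object, FarrowingEvent]]:
    """Lazily generate a cohort; see :func:`simulate_cohort`."""
    if n < 1:
        raise ValidationError(f"cohort size must be >= 1, got {n}")
    if parameter_draws is None:
        parameter_draws = DEFAULT_PARAMETER_DRAWS
    for i in range(n):
        cfg = _member_config(base_config, i, seed, parameter_draws)
        yield simulate_sow(cfg, sow_id=f"sow{i:03d}", as_track=as_tracks)


def simulate_cohort(
    n: int,
    base_config: SimConfig = SimConfig(),
    parameter_draws: Optional[dict] = None,
    seed: int = 0,
    as_tracks: bool = False,
) -> list[tuple[object, FarrowingEvent]]:
    """n independent sows with per-sow parameter draws and matching labels.

    ``parameter_draws`` maps SimConfig field names to draw specs:
    ``("uniform", lo, hi)``, ``("normal", mu, sd)`` or ``("constant", v)``;
    the default draws nest-building start uniformly 8-20 h before onset.
    Fixed seed, identical cohort on re-run.  ``as_tracks=True`` returns
    observed :class:`~nestwatch.activity.CentroidTrack` objects instead of
    per-frame detection lists (cheaper for large cohorts).
    """
    return list(iter_cohort(n, base_config, parameter_draws, seed, as_tracks))
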