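# Methods

`nestwatch` predicts farrowing (parturition in pigs) from computer-vision
activity monitoring.  An upstream object detector supplies per-frame sow
bounding boxes; everything downstream of the detector — activity
computation, trend estimation, the two-stage nest-building alarms, and
cohort evaluation — is implemented here.  This note describes the models,
the parameters that matter, the synthetic data the package is tested on,
and the design choices that were genuinely open.

## Pipeline

1. **Centroid selection.** Per frame, the centroid of the highest-scoring
   detection (ties: larger box, then first listed).  Empty frames leave
   gaps; they are never silently dropped.
2. **Down-sampling.** The 1 fps centroid track is optionally resampled to
   40, 20, 5 or 1 frames/min, or 12 or 4 frames/h (nearest source sample
   within half a target interval).
3. **Activity.** Euclidean distance between consecutive available
   centroids, in pixels per sampling interval.  Distances bridged across
   gaps are flagged.  The measure is translation- and rotation-invariant,
   and summed path length can only shrink under down-sampling (triangle
   inequality).
4. **Smoothing.** Trailing mean over a 24 h window, evaluated every
   15 min; the first 12 h are discarded as warm-up.  A trailing (not
   centered) window keeps the statistic causal, so the alarm chain is
   real-time capable; a full window cancels any 24 h-periodic component
   exactly, which is what removes the diurnal rhythm.  Before 24 h of
   history has accrued, the partial (≥ 12 h) window is used.
5. **Trend.** Integrated-random-walk (IRW) state space model on the 15 min
   grid: level `T_t` driven by a random-walk slope `S_t`,
   observation `y_t = T_t + e_t`.  Kalman filtering plus fixed-interval
   (RTS) smoothing.  The smoothed level is exactly the minimiser of
   `Σ(y_t − T_t)² + (1/nvr)·Σ(ΔΔT_t)²` — a Hodrick–Prescott-type penalty
   with `λ = 1/nvr` — which the test suite exploits as an independent
   oracle (agreement < 1e-6 for n = 200 across nvr from 1e-6 to 1).
6. **Alarms.** The trend model is fitted on the first 48 h of the smoothed
   series and the window expands in 15 min steps.  When the newest
   observation exceeds the upper confidence bound of the trend at that grid
   point, the *first-stage* alarm marks the beginning of nest-building;
   when, later, an observation falls below the lower bound, the
   *second-stage* alarm marks its end (the proposed trigger for temporary
   crate confinement) and processing stops.
7. **Evaluation.** First-stage alarms are true positives inside the 48 h
   pre-onset window, false alarms earlier, `after_onset` at or past onset
   (strict boundary).  Second-stage alarms are valid after the first stage
   and not later than the end of farrowing.  Proportions use all sows in
   the denominator; alarm-lead quartiles use sows with the relevant alarm,
   with linear interpolation between order statistics.  Because the
   denominator for second-stage proportions is ambiguous, both all-sow and
   given-first-stage versions are reported.

## The IRW trend model in detail

State `[T_t, S_t]`, transition `[[1, 1], [0, 1]]`, observation `[1, 0]`.
The slope innovation `ζ_t ~ N(0, q)` enters level and slope through the
same increment (`T_t − T_{t−1} = S_t`, `S_t = S_{t−1} + ζ_t`), so the
second difference of the level is exactly `ζ_t` and the smoothed level is
identical to that of the classical slope-noise-only parametrisation; this
timing is used because it admits an exact diffuse start: conditional on the
first two observations, `[T_1, S_1]` has mean `[y_1, y_1 − y_0]` and
covariance `r·[[1, 1], [1, 2]]` under a flat prior, and `T_0 = T_1 − S_1`
holds exactly.  The exact start is what lets the smoother match the
penalised-least-squares oracle to near machine precision; a finite
"large" prior variance would leave discrepancies at the tested tolerance.
`IRWParams.init_variance` optionally restores a proper large prior for
experimentation.

Only the noise variance ratio `nvr = q/r` affects the estimated trend
(`r` cancels from the Kalman gain).  `r` is estimated as the mean squared
standardised one-step innovation from the same pass run with `r = 1`, and
only scales the confidence bounds — which makes the alarm rule fully
scale-free: multiplying the input series by any `k > 0` leaves alarm times
unchanged.

An expanding-window refit of the smoother is mathematically identical to a
single forward filter pass: the smoothed state at a window's final point
equals the filtered state there, and the running `r̂` is a cumulative mean
of standardised innovations.  `detect_alarms` therefore runs in O(n) for
the whole monitoring period; the equivalence with the literal refit loop is
asserted in the test suite.

## Calibration of the confidence band

Under the IRW model's own null, the newest observation exceeds the
`z`-bound of the filtered trend with probability `Φ̄(z·√p)`, where `p` is
the steady-state predicted level variance (in units of `r`) from the
Riccati recursion.  `p = 1` — the point where the `z = 1.96` band is
honestly calibrated at 2.5 % per step — occurs at `nvr = 1/18`.  The test
suite verifies the empirical exceedance rate against this matched-null
theory.

For monitoring, per-step calibration is not the operating requirement: a
sow is watched for days, across hundreds of 15 min decisions, and the alarm
must stay quiet through all of them until nest-building begins.  Real
activity series contain persistent behavioural fluctuations (resting,
feeding and standing bouts) that a stiff trend does not absorb; the trend's
nominal standard error understates the scale of those deviations by a
factor of roughly two.  Both hyper-parameters of the rule — the noise
ratio and the CI limit — are therefore treated as free operating
parameters, as they are in the method's lineage, and were calibrated once
on synthetic exploration cohorts (20–25 sows, seeds disjoint from those
used anywhere else in the package):

* `nvr = 1e-3` on the 15 min grid (a stiff trend with multi-hour effective
  smoothing, so a sustained nest-building ramp accumulates deviation);
* `ci_multiplier = 6.0` for the alarm path (`ALARM_CI_MULTIPLIER`).

At this operating point the synthetic cohorts at realistic noise reproduce
the qualitative behaviour expected of the method: the large majority of
sows get a first-stage alarm inside the 48 h window with a median lead of
roughly half a day, the second-stage alarm lands one to a few hours before
onset, false alarms (earlier than 48 h) are rare, and a minority of sows
are missed.  Plain `irw_smooth` keeps the conventional `z = 1.96` bounds
for reporting.  Both values are configuration-exposed and must be re-tuned
if the input variable changes (different smoothing window, body-part-level
activity, other species).

## Synthetic data: what it emulates, and what it does not

`SimConfig` describes one sow over ~144 h (pen stocking about five days
before expected farrowing, onset at 120 h by default):

* **Kinematics** — step directions uniform on the circle, magnitudes
  exponential with mean `activity_profile(t)`, reflection at the pen
  walls.  `baseline_step` = 3 px/frame at 1 fps in an 800 × 600 px pen.
* **Diurnal rhythm** — sinusoidal modulation (`diurnal_amplitude` = 0.3,
  period 24 h).
* **Behavioural bouts** — a mean-one log-Ornstein–Uhlenbeck modulation
  (`behavioral_sd` = 0.25, correlation time 3 h).  This component is
  essential, not cosmetic: with pure sampling noise the smoothed series is
  a degenerate null for a self-normalising band rule (the band adapts to
  whatever noise exists, so the crossing rate is invariant to noise
  amplitude and no threshold separates "normal" from "surge").  Real
  series are dominated by persistent bout structure that the trend tracks.
* **Nest-building surge** — piecewise-linear factor rising from 1 at
  `onset − surge_start_offset` (drawn U(8, 20) h across a cohort) to
  `surge_gain` = 4 at `onset − 4 h`, declining to `post_peak_floor` = 0.5
  at onset, holding through farrowing (4 h), then returning to 1.  The
  generated label onset is exactly the onset used to position the surge.
* **Detector noise** — isotropic centroid jitter (1 px), independent
  missed frames (2 %), and decoy episodes: intervals (mean 5 min,
  stationary fraction `false_rate` = 1 %) during which the sow goes
  undetected and a static false detection at a fixed pen coordinate is
  reported instead.  Episodes produce a pair of pen-scale distance
  outliers whose damage to the 24 h mean is inversely proportional to the
  number of samples in the window — which is the mechanism that degrades
  prediction at low frame rates, where a window holds 96 samples instead
  of 28 800.
* **Low-noise conditions** (`LOW_NOISE_OVERRIDES`): halved bout
  variability and jitter, 1 % misses, no decoy episodes.  Used for
  parameter-recovery experiments that ask whether the machinery recovers a
  known surge.

Per-sow streams are seeded independently from `(cohort seed, sow index)`;
identical seeds give bitwise-identical cohorts.  A vectorised path
(`simulate_observed_track`) produces exactly the track that the per-frame
object path plus centroid selection would, and the equivalence is tested.

Not emulated: piglets, posture taxonomies, nest-building sub-behaviours,
pen furniture, camera distortion, or realistic score distributions.
Passing tests on this generator show that the chain recovers the kind of
surge-over-bouts structure the model class assumes; they do not quantify
performance on real barns, breeds or detectors.

## Problem sizes

Synthetic experiments use 50-sow cohorts at 1 fps source rate (518 401
frames per sow over 144 h), analysed at 1 fpm for surge recovery and at
20 fpm / 4 fph for the frame-rate comparison; smoother–oracle checks use
20 series of length 200; the null-calibration experiment uses 50
stationary series of length 529 (the grid length of a 144 h recording).
These sizes keep every experiment deterministic and desk-scale while
leaving binomial error bars small relative to the effects measured.

## Numerical and design choices

* Timestamps are float seconds from stream start; every quantity of
  interest is an offset to farrowing onset, so calendar anchoring is
  metadata.
* Distances are px per sampling interval (not px/s): the series is
  rate-dependent by design; comparability across rates is handled by the
  scale-free alarm rule and, for presentation, per-sow min–max
  normalisation (constant series map to zero).
* Windows use available samples only; no imputation across gaps.
* A single exceedance triggers an alarm (no debouncing); the per-decision
  trace is recorded so users can impose persistence rules downstream.
* Monitoring continues across the first-stage alarm with the same
  expanding window; there is no re-anchoring.
* An alarm at exactly the onset is classified `after_onset`; exactly 48 h
  before onset is a true positive.
* `estimate_nvr_mle` (profile likelihood) is provided as a utility but is
  not on the default path: the default `nvr` is a documented operating
  choice, not re-estimated per sow.

## Known limitations

* The CI multiplier and noise ratio were calibrated on this package's own
  synthetic generator; real deployments need a calibration period on real
  pens.
* The single-exceedance rule benefits from fresh noise at the decision
  point; at low frame rates this can partially mask degradation when the
  surge is strong relative to the noise floor.
* One sow per pen stream is assumed (`pen_id` doubles as `sow_id`);
  multi-sow assignment is out of scope.
* The expanding-window `r̂` is a cumulative mean, so early high-variance
  episodes widen the band for the remainder of a run.
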