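import dataclasses

import numpy as np
import pytest

from nestwatch.activity import euclidean_activity, track_from_frames
from nestwatch.errors import ValidationError
from nestwatch.synthetic import (
    DEFAULT_PARAMETER_DRAWS,
    SimConfig,
    activity_profile,
    inject_detection_noise,
    iter_cohort,
    simulate_cohort,
    simulate_observed_track,
    simulate_sow,
    simulate_trajectory,
    _member_config,
)

QUIET = dict(diurnal_amplitude=0.0, behavioral_sd=0.0, jitter_sd=0.0,
             miss_rate=0.0, false_rate=0.0)


class TestActivityProfile:
    def test_all_modulation_off_is_flat(self):
        cfg = SimConfig(diurnal_amplitude=0.0, surge_gain=1.0, post_peak_floor=1.0)
        t = np.linspace(0, cfg.duration_h, 500)
        np.testing.assert_allclose(activity_profile(cfg, t), cfg.baseline_step)

    def test_peak_value_at_surge_peak(self):
        cfg = SimConfig(diurnal_amplitude=0.0)
        t_peak = cfg.farrowing_onset_h - cfg.surge_peak_offset_h
        assert activity_profile(cfg, t_peak) == pytest.approx(
            cfg.baseline_step * cfg.surge_gain
        )

    def test_pre_surge_day_integrates_to_baseline(self):
        """The diurnal sinusoid contributes nothing over a full day."""
        cfg = SimConfig(diurnal_amplitude=0.4)
        t = np.linspace(24.0, 48.0, 200001)  # well before the surge
        integral = np.trapezoid(activity_profile(cfg, t), t)
        assert integral == pytest.approx(cfg.baseline_step * 24.0, rel=1e-6)

    def test_out_of_domain_rejected(self):
        cfg = SimConfig()
        with pytest.raises(ValidationError):
            activity_profile(cfg, -0.1)
        with pytest.raises(ValidationError):
            activity_profile(cfg, cfg.duration_h + 1.0)

    def test_floor_during_farrowing_and_recovery_after(self):
        cfg = SimConfig(diurnal_amplitude=0.0)
        during = cfg.farrowing_onset_h + cfg.farrowing_duration_h / 2
        after = cfg.farrowing_onset_h + cfg.farrowing_duration_h + 1.0
        assert activity_profile(cfg, during) == pytest.approx(
            cfg.baseline_step * cfg.post_peak_floor
        )
        assert activity_profile(cfg, after) == pytest.approx(cfg.baseline_step)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(surge_start_offset_h=2.0, surge_peak_offset_h=4.0)
        with pytest.raises(ValidationError):
            SimConfig(miss_rate=1.5)
        with pytest.raises(ValidationError):
            SimConfig(surge_gain=0.5)


class TestTrajectory:
    def test_zero_baseline_freezes_sow(self):
        cfg = SimConfig(duration_h=1.0, baseline_step=0.0, **{k: v for k, v in QUIET.items()
                                                              if k != "jitter_sd"})
        track = simulate_trajectory(cfg)
        assert np.all(track.xy == track.xy[0])

    def test_same_seed_same_track(self):
        cfg = SimConfig(duration_h=2.0, seed=99)
        a, b = simulate_trajectory(cfg), simulate_trajectory(cfg)
        np.testing.assert_array_equal(a.xy, b.xy)
        np.testing.assert_array_equal(a.times, b.times)

    def test_centroids_stay_inside_pen(self):
        cfg = SimConfig(duration_h=6.0, baseline_step=40.0, seed=3)  # fast sow
        track = simulate_trajectory(cfg)
        assert np.all(track.xy[:, 0] >= 0) and np.all(track.xy[:, 0] <= cfg.pen_width)
        assert np.all(track.xy[:, 1] >= 0) and np.all(track.xy[:, 1] <= cfg.pen_height)

    def test_mean_step_matches_profile(self):
        """Monte-Carlo: mean displacement ~ configured baseline (3 SE)."""
        cfg = SimConfig(duration_h=3.0, diurnal_amplitude=0.0, behavioral_sd=0.0,
                        seed=7)  # 10800 frames, pre-surge
        track = simulate_trajectory(cfg)
        d = euclidean_activity(track).values
        se = d.std() / np.sqrt(len(d))
        assert abs(d.mean() - cfg.baseline_step) < 3 * se

    def test_uniform_grid_at_source_rate(self):
        cfg = SimConfig(duration_h=1.0, source_rate="1fpm")
        track = simulate_trajectory(cfg)
        np.testing.assert_array_equal(np.diff(track.times), 60.0)


class TestDetectionNoise:
    def test_noise_off_reproduces_track(self):
        cfg = SimConfig(duration_h=0.5, **QUIET)
        track = simulate_trajectory(cfg)
        frames = inject_detection_noise(track, cfg)
        assert len(frames) == len(track)
        sel = track_from_frames(frames, "sow")
        np.testing.assert_allclose(sel.xy, track.xy, atol=1e-12)

    def test_all_frames_missed(self):
        cfg = SimConfig(duration_h=0.5, miss_rate=1.0, false_rate=0.0)
        frames = inject_detection_noise(simulate_trajectory(cfg), cfg)
        assert all(not f.detections for f in frames)

    def test_decoy_episode_fraction(self):
        """Stationary decoy fraction ~ false_rate (binomial-scale tolerance)."""
        cfg = SimConfig(duration_h=24.0, false_rate=0.1, decoy_duration_s=300.0,
                        miss_rate=0.0, seed=21)
        frames = inject_detection_noise(simulate_trajectory(cfg), cfg)
        decoy = [f for f in frames if f.detections
                 and f.detections[0].box.centroid == cfg.decoy_position]
        frac = len(decoy) / len(frames)
        # episodes are correlated: allow 3 SE with effective n = number of episodes
        n_episodes = 0.1 * 24 * 3600 / 300.0
        se = 0.1 / np.sqrt(n_episodes)
        assert abs(frac - 0.1) < 3 * se

    def test_vectorized_observed_track_equals_object_path(self):
        cfg = SimConfig(duration_h=2.0, seed=5)
        frames, _ = simulate_sow(cfg, "s")
        via_objects = track_from_frames(frames, "s")
        direct = simulate_observed_track(cfg, "s")
        np.testing.assert_array_equal(via_objects.times, direct.times)
        np.testing.assert_allclose(via_objects.xy, direct.xy, atol=1e-12)


class TestCohort:
    def test_singleton_composes_member_simulation(self):
        base = SimConfig(duration_h=2.0)
        [(frames, event)] = simulate_cohort(1, base, seed=4)
        member = _member_config(base, 0, 4, DEFAULT_PARAMETER_DRAWS)
        frames2, event2 = simulate_sow(member, sow_id="sow000")
        assert event == event2
        assert [len(f.detections) for f in frames] == [len(f.detections) for f in frames2]

    def test_cohort_reproducible(self):
        base = SimConfig(duration_h=2.0)
        a = simulate_cohort(5, base, seed=11, as_tracks=True)
        b = simulate_cohort(5, base, seed=11, as_tracks=True)
        for (ta, ea), (tb, eb) in zip(a, b):
            assert ea == eb
            np.testing.assert_array_equal(ta.xy, tb.xy)

    def test_surge_start_draws_match_configured_distribution(self):
        n = 200
        draws = [
            _member_config(SimConfig(), i, 13, DEFAULT_PARAMETER_DRAWS).surge_start_offset_h
            for i in range(n)
        ]
        draws = np.asarray(draws)
        assert draws.min() > 8.0 and draws.max() < 20.0
        se = np.sqrt(12.0**2 / 12 / n)   # SD of U(8,20) is 12/sqrt(12)
        assert abs(draws.mean() - 14.0) < 3 * se

    def test_label_onset_equals_surge_positioning(self):
        """No leakage: the label is exactly the onset the surge was built from."""
        base = SimConfig(duration_h=30.0, farrowing_onset_h=25.0)
        for stream, event in iter_cohort(3, base, seed=2, as_tracks=True):
            assert event.onset == 25.0 * 3600.0
            assert event.end == (25.0 + base.farrowing_duration_h) * 3600.0

    def test_invalid_cohort_size(self):
        with pytest.raises(ValidationError):
            simulate_cohort(0, SimConfig())


def test_zero_noise_zero_motion_gives_zero_activity():
    cfg = SimConfig(duration_h=1.0, baseline_step=0.0, surge_gain=1.0,
                    post_peak_floor=1.0, **QUIET)
    track = simulate_observed_track(cfg)
    d = euclidean_activity(track).values
    np.testing.assert_array_equal(d, 0.0)
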