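import numpy as np
import pytest

from nestwatch.activity import (
    downsample,
    euclidean_activity,
    normalize,
    rate_interval,
    select_centroid,
    sliding_mean,
)
from nestwatch.detections_io import BoundingBox, Detection, DetectionFrame
from nestwatch.errors import ConfigurationError, InsufficientDataError

from conftest import HOUR, make_activity, make_smoothed, make_track


def det(x, y, w, h, score):
    return Detection(BoundingBox(x, y, w, h), score)


class TestSelectCentroid:
    def test_empty_frame_gives_none(self):
        assert select_centroid(DetectionFrame("p", 0.0)) is None

    def test_single_detection(self):
        frame = DetectionFrame("p", 0.0, [det(0, 0, 4, 4, 0.5)])
        assert select_centroid(frame) == (2.0, 2.0)

    def test_highest_score_wins(self):
        frame = DetectionFrame("p", 0.0, [det(0, 0, 2, 2, 0.3), det(10, 10, 2, 2, 0.9)])
        assert select_centroid(frame) == (11.0, 11.0)

    def test_score_tie_broken_by_area_then_order(self):
        frame = DetectionFrame("p", 0.0, [
            det(0, 0, 4, 3, 0.7),    # area 12
            det(10, 10, 6, 4, 0.7),  # area 24 -> wins
        ])
        assert select_centroid(frame) == (13.0, 12.0)
        frame2 = DetectionFrame("p", 0.0, [
            det(0, 0, 4, 6, 0.7), det(10, 10, 6, 4, 0.7)  # equal area: first listed
        ])
        assert select_centroid(frame2) == (2.0, 3.0)


class TestDownsample:
    def test_same_rate_is_identity(self):
        track = make_track([0, 1, 2, 3], [[0, 0], [1, 0], [2, 0], [3, 0]])
        out = downsample(track, "1fps")
        np.testing.assert_array_equal(out.times, track.times)
        np.testing.assert_array_equal(out.xy, track.xy)

    def test_600s_of_1fps_to_1fpm(self):
        times = np.arange(600.0)
        xy = np.column_stack([times, np.zeros_like(times)])
        out = downsample(make_track(times, xy), "1fpm")
        np.testing.assert_array_equal(out.times, 60.0 * np.arange(10))
        np.testing.assert_array_equal(out.xy[:, 0], 60.0 * np.arange(10))

    def test_4fph_grid_spacing_is_900s(self):
        times = np.arange(0, 7200.0)
        xy = np.zeros((len(times), 2))
        out = downsample(make_track(times, xy), "4fph")
        assert rate_interval("4fph") == 900.0
        np.testing.assert_array_equal(np.diff(out.times), 900.0)

    def test_gap_with_no_nearby_source_point_left_absent(self):
        times = np.array([0.0, 1.0, 2.0, 500.0, 540.0, 600.0])
        out = downsample(make_track(times, np.zeros((6, 2))), "1fpm")
        # grid 0,60,...,600: only 0 (exact), 480<-500? |500-480|=20<=30 yes,
        # 540 exact, 600 exact; 60..420 have nothing within 30 s
        assert list(out.times) == [0.0, 480.0, 540.0, 600.0]

    def test_upsampling_rejected(self):
        track = make_track([0.0, 60.0], np.zeros((2, 2)), rate="1fpm")
        with pytest.raises(ConfigurationError):
            downsample(track, "1fps")

    def test_unknown_rate_rejected(self):
        track = make_track([0.0, 1.0], np.zeros((2, 2)))
        with pytest.raises(ConfigurationError):
            downsample(track, "2fps")


class TestEuclideanActivity:
    def test_constant_centroid_gives_zero(self):
        track = make_track(np.arange(5.0), np.ones((5, 2)))
        series = euclidean_activity(track)
        np.testing.assert_array_equal(series.values, 0.0)

    def test_three_four_five_triangle(self):
        n = 10
        xy = np.column_stack([3.0 * np.arange(n), 4.0 * np.arange(n)])
        series = euclidean_activity(make_track(np.arange(float(n)), xy))
        np.testing.assert_allclose(series.values, 5.0)

    def test_matches_brute_force_recomputation(self, rng):
        xy = rng.normal(0, 10, (1000, 2)).cumsum(axis=0)
        track = make_track(np.arange(1000.0), xy)
        series = euclidean_activity(track)
        for i in rng.integers(0, 999, 50):
            d = np.sqrt((xy[i + 1, 0] - xy[i, 0]) ** 2 + (xy[i + 1, 1] - xy[i, 1]) ** 2)
            assert series.values[i] == pytest.approx(d, abs=1e-12)

    def test_gap_bridged_and_flagged(self):
        track = make_track([0.0, 1.0, 5.0], [[0, 0], [1, 0], [2, 0]])
        series = euclidean_activity(track)
        np.testing.assert_array_equal(series.values, [1.0, 1.0])
        np.testing.assert_array_equal(series.gap_flags, [False, True])

    def test_short_track_warns_and_returns_empty(self):
        track = make_track([0.0], [[1, 1]])
        with pytest.warns(UserWarning):
            series = euclidean_activity(track)
        assert len(series) == 0

    def test_translation_and_rotation_invariance(self, rng):
        xy = rng.normal(0, 5, (200, 2)).cumsum(axis=0)
        track = make_track(np.arange(200.0), xy)
        base = euclidean_activity(track).values
        shifted = euclidean_activity(make_track(track.times, xy + [120.0, -40.0])).values
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rotated = euclidean_activity(make_track(track.times, xy @ R.T)).values
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        np.testing.assert_allclose(rotated, base, atol=1e-9)

    def test_downsampling_shortens_total_path(self, rng):
        """Triangle inequality: summed distances can only drop at lower rates."""
        xy = rng.normal(0, 3, (7200, 2)).cumsum(axis=0)
        track = make_track(np.arange(7200.0), xy)
        total = {"1fps": euclidean_activity(track).values.sum()}
        for rate in ("1fpm", "4fph"):
            total[rate] = euclidean_activity(downsample(track, rate)).values.sum()
        assert total["1fpm"] <= total["1fps"]
        assert total["4fph"] <= total["1fpm"]


class TestSlidingMean:
    def test_constant_series_stays_constant(self):
        series = make_activity(np.full(3000, 4.2))
        out = sliding_mean(series)
        np.testing.assert_allclose(out.values, 4.2, atol=1e-12)
        np.testing.assert_array_equal(np.diff(out.times), 900.0)

    def test_grid_starts_after_warmup(self):
        series = make_activity(np.ones(2000))
        out = sliding_mean(series)
        assert out.times[0] == series.times[0] + 12 * HOUR

    def test_linear_ramp_full_window_mean(self):
        # d(t) = a*t sampled every 60 s over 3 days; with a full 24 h trailing
        # window the mean sits at the window midpoint: a*(t - 12 h + 30 s)
        a = 0.001
        n = 3 * 1440
        series = make_activity(a * 60.0 * (1 + np.arange(n)))
        out = sliding_mean(series)
        full = out.times >= series.times[0] + 24 * HOUR
        expected = a * (out.times[full] - 12 * HOUR + 30.0)
        np.testing.assert_allclose(out.values[full], expected, rtol=1e-9)

    def test_diurnal_sinusoid_averages_out(self):
        # pure 24 h sinusoid on a constant: full windows remove the rhythm
        t = 60.0 * (1 + np.arange(4 * 1440))
        series = make_activity(5.0 + 2.0 * np.sin(2 * np.pi * t / (24 * HOUR)))
        out = sliding_mean(series)
        full = out.times >= series.times[0] + 24 * HOUR
        np.testing.assert_allclose(out.values[full], 5.0, atol=1e-3)

    def test_pointwise_monotone(self, rng):
        base = rng.exponential(2.0, 3000)
        lo = make_activity(base)
        hi = make_activity(base + rng.uniform(0, 1, 3000))
        out_lo, out_hi = sliding_mean(lo), sliding_mean(hi)
        assert np.all(out_hi.values >= out_lo.values)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError, match="insufficient history"):
            sliding_mean(make_activity(np.ones(100)))  # 100 min << 12 h


class TestNormalize:
    def test_min_max_scaling(self):
        out = normalize(make_smoothed([2.0, 4.0, 6.0]))
        np.testing.assert_array_equal(out.values, [0.0, 0.5, 1.0])

    def test_constant_maps_to_zero(self):
        out = normalize(make_smoothed([3.0, 3.0, 3.0]))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_idempotent(self, rng):
        series = make_smoothed(rng.normal(10, 2, 40))
        once = normalize(series)
        twice = normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-12)
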