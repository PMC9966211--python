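import numpy as np
import pytest

from nestwatch.activity import ActivitySeries, CentroidTrack, SmoothedActivitySeries

HOUR = 3600.0


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_track(times, xy, sow_id="sow", rate="1fps"):
    return CentroidTrack(sow_id=sow_id, rate=rate, times=np.asarray(times, float),
                         xy=np.asarray(xy, float))


def make_smoothed(values, step=900.0, sow_id="sow", rate="1fpm", t0=0.0):
    values = np.asarray(values, float)
    times = t0 + step * np.arange(len(values))
    return SmoothedActivitySeries(sow_id=sow_id, rate=rate, times=times, values=values)


def make_activity(values, step=60.0, sow_id="sow", rate="1fpm"):
    values = np.asarray(values, float)
    times = step * (1 + np.arange(len(values)))
    return ActivitySeries(sow_id=sow_id, rate=rate, times=times, values=values)
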