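"""Shared builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk
except CSVs the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dbdp.timeseries_io import BioSeries, Channel


def make_series(channel, values, start="2021-01-04 00:00:00", freq="min",
                interval=60.0, subject_id="test"):
    """A BioSeries on a uniform grid from a plain list of values."""
    idx = pd.date_range(start, periods=len(values), freq=freq)
    return BioSeries(channel, pd.Series(np.asarray(values, dtype=float), index=idx),
                     interval, subject_id)


def interval_iou(a, b):
    """Intersection-over-union of two (start, end) timestamp intervals."""
    inter = max((min(a[1], b[1]) - max(a[0], b[0])).total_seconds(), 0.0)
    union = (max(a[1], b[1]) - min(a[0], b[0])).total_seconds()
    return inter / union if union else 0.0


def recovery_iou(truth_intervals, episodes, min_seconds=3600.0):
    """Mean best-match IoU of true sleep intervals against detections."""
    scores = []
    for ti in truth_intervals:
        if (ti[1] - ti[0]).total_seconds() < min_seconds:
            continue
        scores.append(max((interval_iou(ti, (e.start, e.end)) for e in episodes),
                          default=0.0))
    return float(np.mean(scores))


@pytest.fixture
def constant_hr():
    return make_series(Channel.HEART_RATE, [60.0] * 1440)


@pytest.fixture
def zero_steps():
    return make_series(Channel.STEPS, [0.0] * 1440)


def write_csv(path, series, time_column="Time", value_column="Value"):
    frame = pd.DataFrame({
        time_column: series.index.strftime("%Y-%m-%dT%H:%M:%S"),
        value_column: series.values,
    })
    frame.to_csv(path, index=False)
    return path
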