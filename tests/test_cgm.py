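"""Glucose metric catalog: hand examples, brute-force oracles, invariants."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest

from dbdp.cgm import (METRIC_CATALOG, GlucoseTrace, RangeConfig, basic_stats,
                      compute_all_metrics, day_to_day, hba1c_estimates,
                      lowess_trend, mage, range_stats, risk_indices,
                      variability_stats)
from dbdp.errors import DegenerateSmoothingError
from dbdp.synthetic import CGMSimParams, simulate_cgm
from dbdp.timeseries_io import BioSeries, Channel

from conftest import make_series


def glucose_trace(values, start="2021-01-04 00:00:00", freq="5min"):
    return GlucoseTrace(make_series(Channel.GLUCOSE, values, start=start,
                                    freq=freq, interval=300.0))


class TestBasicStats:
    def test_constant(self):
        out = basic_stats(glucose_trace([100.0] * 10))
        assert all(v == 100.0 for v in out.values())

    def test_hand_values(self):
        out = basic_stats(glucose_trace([80.0, 100.0, 120.0]))
        assert out["mean_glucose"] == 100.0
        assert out["median_glucose"] == 100.0

    def test_single_sample(self):
        out = basic_stats(glucose_trace([142.0]))
        assert out["min_glucose"] == out["max_glucose"] == out["q1_glucose"] == 142.0


class TestVariabilityStats:
    def test_constant_all_zero(self):
        # two days of constant glucose: every SD/CV metric is exactly 0
        out = variability_stats(glucose_trace([100.0] * 576))
        assert all(v == 0.0 for v in out.values())

    def test_identical_days_zero_spread(self):
        day = [90.0, 110.0]
        idx = (list(pd.date_range("2021-01-04 08:00", periods=2, freq="1h"))
               + list(pd.date_range("2021-01-05 08:00", periods=2, freq="1h")))
        trace = GlucoseTrace(BioSeries(Channel.GLUCOSE,
                                       pd.Series(day + day, index=pd.DatetimeIndex(idx)),
                                       300.0))
        out = variability_stats(trace)
        assert out["intraday_sd_sd"] == 0.0
        assert out["intraday_cv_sd"] == 0.0

    def test_hand_interday_cv(self):
        values = [100.0] * 575 + [130.0]
        out = variability_stats(glucose_trace(values))
        expected_sd = statistics.stdev(values)
        assert out["interday_sd"] == pytest.approx(expected_sd)
        assert out["interday_cv"] == pytest.approx(100 * expected_sd / statistics.mean(values))

    def test_single_day_absent(self):
        out = variability_stats(glucose_trace([100.0, 120.0, 110.0]))
        assert out["intraday_sd_mean"] is None


class TestRangeStats:
    def test_all_in_range(self):
        out = range_stats(glucose_trace([100.0] * 5))
        assert out["tir_pct"] == 100.0
        assert out["tor_pct"] == 0.0

    def test_hand_split(self):
        out = range_stats(glucose_trace([60.0, 100.0, 200.0, 100.0]))
        assert out["tir_pct"] == 50.0
        assert out["mean_out_range"] == 130.0

    def test_boundaries_inclusive(self):
        out = range_stats(glucose_trace([100.0] * 4), RangeConfig(99.0, 101.0))
        assert out["tir_pct"] == 100.0

    def test_tir_tor_sum_exactly_100(self):
        rng = np.random.default_rng(5)
        out = range_stats(glucose_trace(rng.uniform(40, 300, 100)))
        assert out["tir_pct"] + out["tor_pct"] == 100.0


class TestRiskIndices:
    def test_constant_100_hand_transform(self):
        out = risk_indices(glucose_trace([100.0] * 10))
        f = 1.509 * (math.log(100.0) ** 1.084 - 5.381)
        assert f < 0
        assert out["hbgi"] == 0.0
        assert out["lbgi"] == pytest.approx(10 * f ** 2)
        assert out["lbgi"] == pytest.approx(0.486, abs=0.01)

    def test_j_index_constant_150(self):
        out = risk_indices(glucose_trace([150.0] * 10))
        assert out["j_index"] == pytest.approx(0.001 * 150.0 ** 2)

    def test_risk_fixed_point(self):
        g_zero = math.exp(5.381 ** (1 / 1.084))  # f(g) == 0 exactly
        out = risk_indices(glucose_trace([g_zero] * 10))
        assert out["lbgi"] == pytest.approx(0.0, abs=1e-12)
        assert out["hbgi"] == pytest.approx(0.0, abs=1e-12)

    def test_adrr_needs_two_days(self):
        assert risk_indices(glucose_trace([100.0] * 10))["adrr"] is None
        assert risk_indices(glucose_trace([100.0] * 576))["adrr"] is not None


def brute_force_mage(values, sd_multiplier=1.0):
    """Independent MAGE oracle: explicit smoothing + plateau-collapsed extrema."""
    smoothed = []
    n = len(values)
    for i in range(n):
        lo, hi = max(0, i - 4), min(n, i + 5)
        smoothed.append(sum(values[lo:hi]) / (hi - lo))
    # collapse consecutive equal values so plateaus become single points
    dedup = [smoothed[0]]
    for v in smoothed[1:]:
        if v != dedup[-1]:
            dedup.append(v)
    extrema = [dedup[0]]
    for i in range(1, len(dedup) - 1):
        if (dedup[i] - dedup[i - 1]) * (dedup[i + 1] - dedup[i]) < 0:
            extrema.append(dedup[i])
    if len(dedup) > 1:
        extrema.append(dedup[-1])
    threshold = (statistics.stdev(values) if len(values) > 1 else 0.0) * sd_multiplier
    amps = [abs(b - a) for a, b in zip(extrema, extrema[1:]) if abs(b - a) > threshold]
    return sum(amps) / len(amps) if amps else None


class TestMage:
    def test_constant_absent(self):
        assert mage(glucose_trace([100.0] * 20))["mage"] is None

    def test_square_wave_amplitude(self):
        # alternate 90/150 every 2 h (24 five-minute samples per level)
        values = ([90.0] * 24 + [150.0] * 24) * 6
        assert statistics.stdev(values) < 60
        out = mage(glucose_trace(values))
        assert out["mage"] == pytest.approx(60.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        values = list(100 + 40 * np.sin(np.linspace(0, 20, 400))
                      + rng.normal(0, 5, 400))
        out = mage(glucose_trace(values))
        oracle = brute_force_mage(values)
        assert out["mage"] == pytest.approx(oracle, abs=1e-9)

    def test_pure_noise_bounded(self):
        rng = np.random.default_rng(9)
        sigma = 5.0
        values = list(100 + rng.normal(0, sigma, 500))
        out = mage(glucose_trace(values))
        assert out["mage"] is None or out["mage"] <= 2 * sigma


def brute_force_day_to_day(trace, tolerance_s=150.0):
    """Independent MODD/CONGA24 oracle: all-pairs nearest matching."""
    times = list(trace.index)
    values = list(trace.values)
    diffs = []
    for i, t in enumerate(times):
        target = t - pd.Timedelta(hours=24)
        best_j, best_gap = None, None
        for j, u in enumerate(times):
            gap = abs((u - target).total_seconds())
            if best_gap is None or gap < best_gap:
                best_j, best_gap = j, gap
        if best_gap is not None and best_gap <= tolerance_s:
            diffs.append(values[i] - values[best_j])
    if not diffs:
        return None, None
    modd = sum(abs(d) for d in diffs) / len(diffs)
    conga = statistics.stdev(diffs) if len(diffs) > 1 else None
    return modd, conga


class TestDayToDay:
    def test_identical_days(self):
        values = [90.0, 120.0, 100.0, 95.0] * 2
        idx = (list(pd.date_range("2021-01-04 06:00", periods=4, freq="4h"))
               + list(pd.date_range("2021-01-05 06:00", periods=4, freq="4h")))
        trace = GlucoseTrace(BioSeries(Channel.GLUCOSE,
                                       pd.Series(values, index=pd.DatetimeIndex(idx)),
                                       300.0))
        out = day_to_day(trace)
        assert out["modd"] == 0.0
        assert out["conga24"] == 0.0

    def test_uniform_offset(self):
        day1 = [90.0, 120.0, 100.0, 95.0]
        idx = (list(pd.date_range("2021-01-04 06:00", periods=4, freq="4h"))
               + list(pd.date_range("2021-01-05 06:00", periods=4, freq="4h")))
        trace = GlucoseTrace(BioSeries(
            Channel.GLUCOSE,
            pd.Series(day1 + [v + 10 for v in day1], index=pd.DatetimeIndex(idx)),
            300.0))
        out = day_to_day(trace)
        assert out["modd"] == pytest.approx(10.0)
        assert out["conga24"] == pytest.approx(0.0)

    def test_hand_fixture_matches_bruteforce(self):
        rng = np.random.default_rng(10)
        idx = (list(pd.date_range("2021-01-04 00:00", periods=48, freq="30min"))
               + list(pd.date_range("2021-01-05 00:00", periods=48, freq="30min")))
        values = list(rng.uniform(80, 180, 96))
        trace = GlucoseTrace(BioSeries(Channel.GLUCOSE,
                                       pd.Series(values, index=pd.DatetimeIndex(idx)),
                                       300.0))
        out = day_to_day(trace)
        modd, conga = brute_force_day_to_day(trace)
        assert out["modd"] == pytest.approx(modd, abs=1e-9)
        assert out["conga24"] == pytest.approx(conga, abs=1e-9)

    def test_single_day_absent(self):
        out = day_to_day(glucose_trace([100.0] * 12))
        assert out["modd"] is None


class TestHbA1c:
    def test_hand_arithmetic(self):
        out = hba1c_estimates(glucose_trace([150.0] * 4))
        assert out["gmi_pct"] == pytest.approx(3.31 + 0.02392 * 150, abs=1e-9)
        assert out["ea1c_pct"] == pytest.approx((150 + 46.7) / 28.7, abs=1e-9)

    def test_monotone_in_mean(self):
        low = hba1c_estimates(glucose_trace([100.0] * 4))
        high = hba1c_estimates(glucose_trace([140.0] * 4))
        assert high["gmi_pct"] > low["gmi_pct"]
        assert high["ea1c_pct"] > low["ea1c_pct"]


class TestComputeAllMetrics:
    def test_two_week_trace_has_25_plus(self):
        trace, _ = simulate_cgm(CGMSimParams(seed=0))
        report = compute_all_metrics(trace)
        assert len(report.metrics) == 28
        assert report.present_count() >= 25

    def test_constant_trace_limits(self):
        report = compute_all_metrics(glucose_trace([100.0] * 576))
        assert report["interday_sd"].value == 0.0
        assert report["tir_pct"].value == 100.0
        assert report["mean_glucose"].value == 100.0
        assert not report["mage"].present

    def test_one_day_absences_have_reasons(self):
        report = compute_all_metrics(glucose_trace([100.0, 120.0] * 100))
        assert set(report.metrics) == set(METRIC_CATALOG)
        for name in ("modd", "conga24", "adrr", "intraday_sd_mean"):
            assert not report[name].present
            assert report[name].reason

    def test_offset_shifts_only_location_metrics(self):
        rng = np.random.default_rng(11)
        values = list(rng.uniform(90, 160, 576))
        base = compute_all_metrics(glucose_trace(values))
        shifted = compute_all_metrics(glucose_trace([v + 25 for v in values]))
        for name in ("interday_sd", "intraday_sd_mean", "mage", "modd", "conga24"):
            if base[name].present:
                assert shifted[name].value == pytest.approx(base[name].value, abs=1e-9)
        assert shifted["mean_glucose"].value == pytest.approx(
            base["mean_glucose"].value + 25, abs=1e-9)
        assert shifted["gmi_pct"].value == pytest.approx(
            base["gmi_pct"].value + 0.02392 * 25, abs=1e-9)
        assert shifted["ea1c_pct"].value == pytest.approx(
            base["ea1c_pct"].value + 25 / 28.7, abs=1e-9)

    def test_percent_metrics_in_range(self):
        trace, _ = simulate_cgm(CGMSimParams(seed=1))
        report = compute_all_metrics(trace)
        for name in ("tir_pct", "tor_pct", "por_pct"):
            assert 0.0 <= report[name].value <= 100.0
        assert report["tir_pct"].value + report["tor_pct"].value == 100.0


class TestLowessTrend:
    def test_constant_preserved(self):
        trend = lowess_trend(glucose_trace([100.0] * 20))
        assert np.allclose(trend.values, 100.0)

    def test_linear_reproduced(self):
        values = list(np.linspace(100, 160, 30))
        trend = lowess_trend(glucose_trace(values), frac=1.0)
        assert np.max(np.abs(trend.values - np.array(values))) < 1e-6

    def test_denoises_sinusoid(self):
        rng = np.random.default_rng(12)
        t = np.linspace(0, 4 * np.pi, 400)
        clean = 120 + 30 * np.sin(t)
        noisy = clean + rng.normal(0, 10, 400)
        trend = lowess_trend(glucose_trace(list(noisy)), frac=0.1)
        rmse_raw = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_fit = np.sqrt(np.mean((trend.values - clean) ** 2))
        assert rmse_fit < rmse_raw

    def test_too_few_samples(self):
        with pytest.raises(DegenerateSmoothingError):
            lowess_trend(glucose_trace([100.0] * 5))
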