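"""Exploratory screening of wearable series: data completeness per day and
per hour, outlier flagging, and basic summaries.

Missingness is quantified against the device's nominal sampling grid: an
hour is "complete" when every nominal grid slot in it contains at least one
sample, so oversampling can never exceed 100%. Per-day fractions always use
the full 24-hour denominator so day-by-hour heat-grids stay comparable
across days, including partial first/last days.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError, EmptyInputError
from .timeseries_io import BioSeries, PlausibilityBounds, default_bounds

logger = logging.getLogger(__name__)

__all__ = ["MissingnessSummary", "OutlierReport", "missingness_by_day_hour",
           "flag_outliers", "summarize_series"]


@dataclass(frozen=True)
class MissingnessSummary:
    """Fractions of nominal grid slots containing data, per day and per hour."""

    per_day: dict[datetime.date, float]
    per_day_hour: dict[tuple[datetime.date, int], float]
    expected_per_hour: int
    expected_per_day: int

    def per_day_hour_frame(self) -> pd.DataFrame:
        rows = [(d, h, f) for (d, h), f in sorted(self.per_day_hour.items())]
        return pd.DataFrame(rows, columns=["date", "hour", "fraction"])

    def per_day_frame(self) -> pd.DataFrame:
        rows = sorted(self.per_day.items())
        return pd.DataFrame(rows, columns=["date", "fraction"])

    def heat_grid(self) -> pd.DataFrame:
        """Day x hour matrix of presence fractions (absent hours = 0)."""
        dates = sorted(self.per_day)
        grid = pd.DataFrame(0.0, index=pd.Index(dates, name="date"),
                            columns=pd.RangeIndex(24, name="hour"))
        for (d, h), f in self.per_day_hour.items():
            grid.loc[d, h] = f
        return grid


def missingness_by_day_hour(series: BioSeries,
                            nominal_interval: float | None = None) -> MissingnessSummary:
    """Fraction of nominal grid slots containing >= 1 sample, per (day, hour).

    ``nominal_interval`` (seconds) must divide 3600. The per-hour map covers
    every (date, hour) between the first and last sample inclusive; per-day
    fractions average that date's 24 hourly fractions, counting hours outside
    the observed span as 0.
    """
    if not len(series):
        raise EmptyInputError("missingness of an empty series is undefined")
    interval = int(nominal_interval if nominal_interval is not None else series.nominal_interval)
    if interval <= 0 or 3600 % interval != 0:
        raise ContractError(f"nominal_interval ({interval}s) must divide 3600")
    slots_per_hour = 3600 // interval

    idx = series.index
    slot = idx.floor(f"{interval}s")
    occupied = pd.DatetimeIndex(slot.unique())
    keys = pd.MultiIndex.from_arrays(
        [occupied.normalize().date, occupied.hour, occupied.asi8]
    )
    counts = (
        pd.Series(1, index=keys)
        .groupby(level=[0, 1])
        .size()
    )

    first = idx[0].floor("h")
    last = idx[-1].floor("h")
    hours = pd.date_range(first, last, freq="h")
    per_day_hour: dict[tuple[datetime.date, int], float] = {}
    for ts in hours:
        key = (ts.date(), ts.hour)
        per_day_hour[key] = counts.get(key, 0) / slots_per_hour

    per_day: dict[datetime.date, float] = {}
    for date in pd.date_range(first.normalize(), last.normalize(), freq="D"):
        d = date.date()
        per_day[d] = sum(per_day_hour.get((d, h), 0.0) for h in range(24)) / 24.0

    return MissingnessSummary(per_day, per_day_hour,
                              expected_per_hour=slots_per_hour,
                              expected_per_day=24 * slots_per_hour)


@dataclass(frozen=True)
class OutlierReport:
    """Positions flagged by the plausibility-bounds and spike rules."""

    indices: tuple[int, ...]
    rule: str
    rules_by_index: dict[int, str]
    flagged_count: int


def flag_outliers(series: BioSeries, bounds: PlausibilityBounds | None = None,
                  spike_sd: float = 5.0, window: str = "15min") -> OutlierReport:
    """Flag samples outside bounds or spiking away from the local level.

    The spike rule flags ``|value - rolling median| > spike_sd * robust SD``
    over a trailing 15-minute window, with robust SD = 1.4826 x MAD. Series
    spanning less than one window fall back to the bounds rule alone.
    """
    if spike_sd <= 0:
        raise ContractError("spike_sd must be > 0")
    if bounds is None:
        bounds = default_bounds(series.channel)
    values = series.data
    out_of_bounds = (values < bounds.low) | (values > bounds.high)

    rules: dict[int, str] = {}
    for pos in np.flatnonzero(out_of_bounds.to_numpy()):
        rules[int(pos)] = "bounds"

    span = series.index[-1] - series.index[0] if len(series) else pd.Timedelta(0)
    if len(series) and span >= pd.Timedelta(window):
        roll = values.rolling(window, min_periods=1)
        med = roll.median()
        mad = roll.apply(lambda x: np.median(np.abs(x - np.median(x))), raw=True)
        robust_sd = 1.4826 * mad
        spikes = (values - med).abs() > spike_sd * robust_sd
        for pos in np.flatnonzero(spikes.to_numpy()):
            rules.setdefault(int(pos), "spike")
    else:
        logger.warning("flag_outliers: series shorter than the %s window; "
                       "bounds rule only", window)

    indices = tuple(sorted(rules))
    return OutlierReport(
        indices=indices,
        rule=(f"value outside [{bounds.low:g}, {bounds.high:g}] or "
              f"|value - rolling median({window})| > {spike_sd:g} x 1.4826 x MAD"),
        rules_by_index=rules,
        flagged_count=len(indices),
    )


def summarize_series(series: BioSeries) -> dict[str, float]:
    """Standard descriptive summary (SD uses the n-1 denominator)."""
    if not len(series):
        raise EmptyInputError("cannot summarize an empty series")
    v = series.values
    if len(v) == 1:
        logger.warning("summarize_series: single sample; SD reported as 0")
        sd = 0.0
    else:
        sd = float(np.std(v, ddof=1))
    span = (series.index[-1] - series.index[0]).total_seconds() / 86400.0
    return {
        "n": float(len(v)),
        "mean": float(np.mean(v)),
        "sd": sd,
        "min": float(np.min(v)),
        "q1": float(np.percentile(v, 25)),
        "median": float(np.median(v)),
        "q3": float(np.percentile(v, 75)),
        "max": float(np.max(v)),
        "span_days": span,
    }
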