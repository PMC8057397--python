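"""Device-agnostic ingestion, validation, resampling, and alignment of
wearable time series.

Every downstream module (EDA, resting heart rate, sleep, CGM metrics)
consumes the single-channel :class:`BioSeries` container defined here, so
vendor CSV exports only need a timestamp column and a value column to enter
the pipeline.

Conventions enforced package-wide:

* timestamps are local wall-clock instants (converted to one configured
  timezone at read time, then stored naive);
* resampling bins are half-open ``[t, t + interval)`` and labelled by their
  left edge; windowed operations downstream use half-open ``(t - w, t]``
  lookback windows;
* a missing measurement is an absent sample, never a sentinel value — except
  for the steps channel, where an empty bin inside the observed wear span
  means "no steps" and is zero-filled.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, EmptyInputError

logger = logging.getLogger(__name__)

__all__ = [
    "Channel",
    "BioSeries",
    "PlausibilityBounds",
    "DEFAULT_BOUNDS",
    "default_bounds",
    "read_series",
    "write_series",
    "validate_series",
    "resample_uniform",
    "align_series",
]


class Channel(str, enum.Enum):
    """Physiological channel of a series, fixing its units."""

    HEART_RATE = "heart_rate"  # beats per minute
    STEPS = "steps"            # counts per sampling interval
    GLUCOSE = "glucose"        # mg/dL

    @classmethod
    def coerce(cls, value: "Channel | str") -> "Channel":
        if isinstance(value, cls):
            return value
        aliases = {"hr": cls.HEART_RATE, "heart_rate": cls.HEART_RATE,
                   "steps": cls.STEPS, "glucose": cls.GLUCOSE, "cgm": cls.GLUCOSE}
        try:
            return aliases[str(value).lower()]
        except KeyError:
            raise ContractError(f"unknown channel {value!r}; expected one of "
                                f"{sorted(set(aliases))}") from None


@dataclass(frozen=True)
class BioSeries:
    """A timestamped single-channel physiological series.

    Parameters
    ----------
    channel
        What the values measure (heart rate, steps, glucose).
    data
        ``pandas.Series`` of finite floats indexed by a strictly increasing,
        timezone-naive ``DatetimeIndex`` (local wall clock).
    nominal_interval
        The sampling interval the device aims for, in seconds (> 0).
    subject_id
        Opaque identifier carried through reports.
    """

    channel: Channel
    data: pd.Series
    nominal_interval: float = 60.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", Channel.coerce(self.channel))
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise ContractError("BioSeries requires a DatetimeIndex")
        if self.data.index.tz is not None:
            object.__setattr__(self, "data", self.data.tz_localize(None))
        if len(self.data) and not self.data.index.is_monotonic_increasing:
            raise ContractError("timestamps must be strictly increasing")
        if len(self.data) and self.data.index.has_duplicates:
            raise ContractError("duplicate timestamps are not allowed in a BioSeries")
        values = self.data.to_numpy(dtype=float)
        if len(values) and not np.all(np.isfinite(values)):
            raise ContractError("all values must be finite; drop missing samples instead")
        if self.nominal_interval <= 0:
            raise ContractError("nominal_interval must be > 0")
        object.__setattr__(self, "data", self.data.astype(float))

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def span_days(self) -> int:
        """Number of distinct calendar dates touched by the series."""
        if not len(self.data):
            return 0
        return self.data.index.normalize().nunique()

    def with_data(self, data: pd.Series) -> "BioSeries":
        return BioSeries(self.channel, data, self.nominal_interval, self.subject_id)

    @classmethod
    def from_arrays(cls, channel: Channel | str, timestamps, values,
                    nominal_interval: float = 60.0, subject_id: str = "") -> "BioSeries":
        idx = pd.DatetimeIndex(pd.to_datetime(timestamps))
        return cls(Channel.coerce(channel), pd.Series(np.asarray(values, dtype=float), index=idx),
                   nominal_interval, subject_id)


@dataclass(frozen=True)
class PlausibilityBounds:
    """Inclusive physiological/sensor limits for one channel."""

    channel: Channel
    low: float
    high: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "channel", Channel.coerce(self.channel))
        if not self.low < self.high:
            raise ContractError("bounds require low < high")


#: Physiological/sensor plausibility defaults; all overridable.
DEFAULT_BOUNDS: dict[Channel, PlausibilityBounds] = {
    Channel.HEART_RATE: PlausibilityBounds(Channel.HEART_RATE, 25.0, 250.0),
    Channel.STEPS: PlausibilityBounds(Channel.STEPS, 0.0, 300.0),
    Channel.GLUCOSE: PlausibilityBounds(Channel.GLUCOSE, 20.0, 600.0),
}


def default_bounds(channel: Channel | str) -> PlausibilityBounds:
    return DEFAULT_BOUNDS[Channel.coerce(channel)]


def read_series(path, channel: Channel | str, time_column: str = "Time",
                value_column: str = "Value", timezone: str | None = None,
                nominal_interval: float = 60.0, subject_id: str = "") -> BioSeries:
    """Read one channel from a long-format CSV.

    Rows with unparseable timestamps or non-finite values are skipped with a
    logged warning count. Rows are sorted by timestamp; duplicate timestamps
    are collapsed to the mean of their values (order-independent), with the
    collapse count logged.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    EmptyInputError
        If no row yields a parseable timestamp and finite value.
    """
    frame = pd.read_csv(path)
    for col in (time_column, value_column):
        if col not in frame.columns:
            raise ContractError(f"column {col!r} not found in {path} "
                                f"(columns: {list(frame.columns)})")
    times = pd.to_datetime(frame[time_column], errors="coerce", utc=timezone is not None)
    values = pd.to_numeric(frame[value_column], errors="coerce")
    ok = times.notna() & np.isfinite(values)
    skipped = int((~ok).sum())
    if skipped:
        logger.warning("read_series(%s): skipped %d unparseable row(s)", path, skipped)
    if not ok.any():
        raise EmptyInputError(f"no parseable rows in {path}")
    idx = pd.DatetimeIndex(times[ok])
    if timezone is not None:
        # convert to the configured local timezone, then store wall-clock naive
        idx = idx.tz_convert(timezone).tz_localize(None)
    series = pd.Series(values[ok].to_numpy(dtype=float), index=idx).sort_index()
    if series.index.has_duplicates:
        n_before = len(series)
        series = series.groupby(level=0).mean()
        logger.info("read_series(%s): collapsed %d duplicate-timestamp row(s) by mean",
                    path, n_before - len(series))
    logger.info("read_series(%s): %d samples", path, len(series))
    return BioSeries(Channel.coerce(channel), series, nominal_interval, subject_id)


def write_series(series: BioSeries, path, time_column: str = "Time",
                 value_column: str = "Value") -> None:
    """Write a series back to the CSV dialect :func:`read_series` consumes."""
    frame = pd.DataFrame({
        time_column: series.index.strftime("%Y-%m-%dT%H:%M:%S"),
        value_column: series.values,
    })
    frame.to_csv(path, index=False)


def validate_series(series: BioSeries,
                    bounds: PlausibilityBounds | None = None) -> tuple[BioSeries, int]:
    """Drop samples outside inclusive plausibility bounds.

    Returns the filtered series and the number of rejected samples.
    """
    if bounds is None:
        bounds = default_bounds(series.channel)
    if bounds.channel != series.channel:
        raise ContractError(f"bounds channel {bounds.channel} != series channel {series.channel}")
    keep = (series.data >= bounds.low) & (series.data <= bounds.high)
    rejected = int((~keep).sum())
    if rejected:
        logger.info("validate_series: rejected %d sample(s) outside [%g, %g]",
                    rejected, bounds.low, bounds.high)
    return series.with_data(series.data[keep]), rejected


_AGGREGATORS = {"mean", "sum", "median"}


def resample_uniform(series: BioSeries, interval: float,
                     aggregator: str = "mean") -> BioSeries:
    """Aggregate onto the uniform grid of half-open bins ``[t, t + interval)``.

    Grid timestamps are bin left edges, floor-aligned to ``interval``
    (relative to the Unix epoch), spanning the first through last sample.
    Bins with no samples are absent from the output — except for the steps
    channel, where an empty bin inside the observed wear span is 0 (an idle
    step counter emits nothing, which *is* a measurement of zero steps).
    """
    if interval <= 0:
        raise ContractError("interval must be > 0")
    if aggregator not in _AGGREGATORS:
        raise ContractError(f"aggregator must be one of {sorted(_AGGREGATORS)}")
    if not len(series):
        raise EmptyInputError("cannot resample an empty series")
    rule = pd.Timedelta(seconds=interval)
    resampler = series.data.resample(rule, origin="epoch", label="left", closed="left")
    if aggregator == "mean":
        out = resampler.mean()
    elif aggregator == "median":
        out = resampler.median()
    else:
        out = resampler.sum(min_count=1)  # empty bins -> NaN, handled below
    if series.channel is Channel.STEPS:
        out = out.fillna(0.0)  # empty bin within wear span == no steps
    else:
        out = out.dropna()
    return BioSeries(series.channel, out, interval, series.subject_id)


def align_series(a: BioSeries, b: BioSeries, interval: float,
                 aggregator_a: str | None = None,
                 aggregator_b: str | None = None) -> pd.DataFrame:
    """Resample two channels to a shared grid and keep common timestamps.

    Returns a two-column DataFrame (columns named after the channels, or
    suffixed ``_a``/``_b`` when the channels coincide) indexed by the shared
    grid; only timestamps with a value in BOTH channels are retained. Steps
    default to ``sum`` aggregation, other channels to ``mean``.
    """
    if not len(a) or not len(b):
        raise EmptyInputError("cannot align an empty series")

    def _default(ch: Channel) -> str:
        return "sum" if ch is Channel.STEPS else "mean"

    ga = resample_uniform(a, interval, aggregator_a or _default(a.channel))
    gb = resample_uniform(b, interval, aggregator_b or _default(b.channel))
    name_a, name_b = a.channel.value, b.channel.value
    if name_a == name_b:
        name_a, name_b = f"{name_a}_a", f"{name_b}_b"
    paired = pd.concat(
        {name_a: ga.data, name_b: gb.data}, axis=1, join="inner"
    ).dropna()
    if paired.empty:
        logger.warning("align_series: no overlapping timestamps between channels")
    return paired
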