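"""Glucose and glycemic-variability metrics from continuous glucose
monitor (CGM) traces, plus a LOWESS longitudinal trend.

The catalog comprises 28 named metrics in seven groups:

* basic statistics: mean, median, min, max, q1, q3 (mg/dL);
* variability: between-sample (interday) SD and CV, and per-day (intraday)
  SD/CV aggregated across days by mean, median and SD;
* target range (default 70-180 mg/dL, boundary-inclusive): percent time in
  range (TIR), percent outside (TOR/POR), and subset means;
* risk indices built on the symmetrizing log transform
  ``f(g) = 1.509 * ((ln g)^1.084 - 5.381)`` of glucose in mg/dL:
  LBGI (mean low-tail risk ``10 f^2`` for f < 0), HBGI (high tail), ADRR
  (mean over days of the daily risk-range extremes), and the J-index
  ``0.001 * (mean + SD)^2``;
* MAGE — mean amplitude of glycemic excursions, using the smoothed-extrema
  dialect: local extrema of a 9-point moving average, excursions exceeding
  ``sd_multiplier x`` the overall SD, both directions averaged;
* day-to-day: MODD (mean |g(t) - g(t - 24 h)|) and CONGA24 (SD of the 24-h
  lagged differences), pairing clock times within +/-2.5 min;
* hemoglobin-A1c estimates: GMI = 3.31 + 0.02392 * mean, and
  eA1c = (mean + 46.7) / 28.7, both in percent.

Metrics whose preconditions fail (e.g. MODD on a single day) are reported
as absent with a reason, never silently dropped: every report enumerates
all 28 names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .errors import ContractError, DegenerateSmoothingError, EmptyInputError
from .timeseries_io import BioSeries, Channel

logger = logging.getLogger(__name__)

__all__ = ["GlucoseTrace", "RangeConfig", "MetricValue", "MetricReport",
           "basic_stats", "variability_stats", "range_stats", "risk_indices",
           "mage", "day_to_day", "hba1c_estimates", "compute_all_metrics",
           "lowess_trend", "METRIC_CATALOG"]

#: Every metric name the report enumerates, with units.
METRIC_CATALOG: dict[str, str] = {
    "mean_glucose": "mg/dL", "median_glucose": "mg/dL", "min_glucose": "mg/dL",
    "max_glucose": "mg/dL", "q1_glucose": "mg/dL", "q3_glucose": "mg/dL",
    "interday_sd": "mg/dL", "interday_cv": "%",
    "intraday_sd_mean": "mg/dL", "intraday_sd_median": "mg/dL",
    "intraday_sd_sd": "mg/dL", "intraday_cv_mean": "%",
    "intraday_cv_median": "%", "intraday_cv_sd": "%",
    "tir_pct": "%", "tor_pct": "%", "por_pct": "%",
    "mean_in_range": "mg/dL", "mean_out_range": "mg/dL",
    "lbgi": "risk", "hbgi": "risk", "adrr": "risk", "j_index": "unitless",
    "mage": "mg/dL",
    "modd": "mg/dL", "conga24": "mg/dL",
    "gmi_pct": "%", "ea1c_pct": "%",
}


@dataclass(frozen=True)
class GlucoseTrace:
    """A validated CGM series (mg/dL) with per-sample calendar dates."""

    series: BioSeries

    def __post_init__(self) -> None:
        if self.series.channel is not Channel.GLUCOSE:
            raise ContractError("GlucoseTrace requires a glucose-channel series")
        if not len(self.series):
            raise EmptyInputError("GlucoseTrace requires >= 1 sample")

    @property
    def values(self) -> np.ndarray:
        return self.series.values

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.series.index

    @property
    def day_index(self) -> pd.Series:
        return pd.Series(self.index.normalize().date, index=self.index)

    @property
    def n_days(self) -> int:
        return self.series.span_days

    @classmethod
    def from_arrays(cls, timestamps, values, interval_s: float = 300.0,
                    subject_id: str = "") -> "GlucoseTrace":
        return cls(BioSeries.from_arrays(Channel.GLUCOSE, timestamps, values,
                                         interval_s, subject_id))


@dataclass(frozen=True)
class RangeConfig:
    """Target glucose range (mg/dL), boundary-inclusive; default 70-180."""

    lower: float = 70.0
    upper: float = 180.0

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ContractError("range requires lower < upper")


@dataclass(frozen=True)
class MetricValue:
    value: float | None
    units: str
    present: bool = True
    reason: str = ""


@dataclass(frozen=True)
class MetricReport:
    """Ordered metric-name -> value map covering the full 28-name catalog."""

    metrics: dict[str, MetricValue]
    n_days: int
    n_samples: int

    def present_count(self) -> int:
        return sum(m.present for m in self.metrics.values())

    def __getitem__(self, name: str) -> MetricValue:
        return self.metrics[name]

    def value(self, name: str) -> float | None:
        return self.metrics[name].value

    def to_dict(self) -> dict:
        return {
            "n_days": self.n_days,
            "n_samples": self.n_samples,
            "metrics": {name: {"value": m.value, "units": m.units,
                               "present": m.present, "reason": m.reason}
                        for name, m in self.metrics.items()},
        }


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else 0.0


def basic_stats(trace: GlucoseTrace) -> dict[str, float]:
    """Mean/median/min/max and linearly interpolated quartiles, mg/dL."""
    v = trace.values
    return {
        "mean_glucose": float(np.mean(v)),
        "median_glucose": float(np.median(v)),
        "min_glucose": float(np.min(v)),
        "max_glucose": float(np.max(v)),
        "q1_glucose": float(np.percentile(v, 25)),
        "q3_glucose": float(np.percentile(v, 75)),
    }


def variability_stats(trace: GlucoseTrace) -> dict[str, float | None]:
    """Interday (all-sample) and intraday (per-day) SD and CV.

    Intraday metrics need >= 2 days each with >= 2 samples; otherwise they
    are returned as None (reported absent upstream).
    """
    v = trace.values
    out: dict[str, float | None] = {}
    interday_sd = _sd(v)
    out["interday_sd"] = interday_sd
    out["interday_cv"] = 100.0 * interday_sd / float(np.mean(v))

    by_day = pd.Series(v, index=trace.index).groupby(trace.day_index.to_numpy())
    day_sd, day_cv = [], []
    for _, day_vals in by_day:
        if len(day_vals) >= 2:
            s = _sd(day_vals.to_numpy())
            day_sd.append(s)
            day_cv.append(100.0 * s / float(day_vals.mean()))
    if len(day_sd) >= 2:
        out["intraday_sd_mean"] = float(np.mean(day_sd))
        out["intraday_sd_median"] = float(np.median(day_sd))
        out["intraday_sd_sd"] = _sd(np.asarray(day_sd))
        out["intraday_cv_mean"] = float(np.mean(day_cv))
        out["intraday_cv_median"] = float(np.median(day_cv))
        out["intraday_cv_sd"] = _sd(np.asarray(day_cv))
    else:
        for key in ("intraday_sd_mean", "intraday_sd_median", "intraday_sd_sd",
                    "intraday_cv_mean", "intraday_cv_median", "intraday_cv_sd"):
            out[key] = None
    return out


def range_stats(trace: GlucoseTrace,
                range_config: RangeConfig | None = None) -> dict[str, float | None]:
    """Percent of samples in/out of the target range and subset means."""
    rc = range_config or RangeConfig()
    v = trace.values
    in_range = (v >= rc.lower) & (v <= rc.upper)
    tir = 100.0 * float(in_range.mean())
    return {
        "tir_pct": tir,
        "tor_pct": 100.0 - tir,
        "por_pct": 100.0 - tir,
        "mean_in_range": float(v[in_range].mean()) if in_range.any() else None,
        "mean_out_range": float(v[~in_range].mean()) if (~in_range).any() else None,
    }


def _risk(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Low/high risk components 10*f(g)^2 of the symmetrizing transform."""
    f = 1.509 * (np.log(values) ** 1.084 - 5.381)
    rl = np.where(f < 0, 10.0 * f ** 2, 0.0)
    rh = np.where(f > 0, 10.0 * f ** 2, 0.0)
    return rl, rh


def risk_indices(trace: GlucoseTrace) -> dict[str, float | None]:
    """LBGI, HBGI, ADRR (needs >= 2 days), and the J-index."""
    v = trace.values
    if np.any(v <= 0):
        raise ContractError("risk indices require positive glucose values")
    rl, rh = _risk(v)
    out: dict[str, float | None] = {
        "lbgi": float(np.mean(rl)),
        "hbgi": float(np.mean(rh)),
        "j_index": float(0.001 * (np.mean(v) + _sd(v)) ** 2),
    }
    days = trace.day_index.to_numpy()
    frame = pd.DataFrame({"rl": rl, "rh": rh, "day": days})
    if frame["day"].nunique() >= 2:
        daily = frame.groupby("day").agg(max_rl=("rl", "max"), max_rh=("rh", "max"))
        out["adrr"] = float((daily["max_rl"] + daily["max_rh"]).mean())
    else:
        out["adrr"] = None
    return out


def _local_extrema(values: np.ndarray) -> list[int]:
    """Indices of alternating local extrema, plateau-tolerant.

    The first and last points are included as boundary extrema; interior
    extrema are turning points where the (zero-skipping) slope sign flips.
    """
    n = len(values)
    if n < 2:
        return list(range(n))
    extrema = [0]
    last_sign = 0
    for i in range(1, n):
        diff = values[i] - values[i - 1]
        if diff == 0:
            continue
        sign = 1 if diff > 0 else -1
        if last_sign != 0 and sign != last_sign:
            extrema.append(i - 1)
        last_sign = sign
    extrema.append(n - 1)
    return extrema


def mage(trace: GlucoseTrace, sd_multiplier: float = 1.0) -> dict[str, float | None]:
    """Mean amplitude of glycemic excursions (smoothed-extrema dialect).

    The trace is smoothed with a 9-point moving average; consecutive local
    extrema of the smoothed trace whose difference exceeds
    ``sd_multiplier x`` the overall (interday) SD count as excursions, and
    MAGE is the mean of their absolute amplitudes (None when no excursion
    qualifies, e.g. on a constant trace).
    """
    if len(trace.values) < 3:
        return {"mage": None}
    smoothed = (pd.Series(trace.values)
                .rolling(9, center=True, min_periods=1).mean().to_numpy())
    threshold = sd_multiplier * _sd(trace.values)
    ext = _local_extrema(smoothed)
    amplitudes = [abs(smoothed[b] - smoothed[a]) for a, b in zip(ext, ext[1:])]
    qualifying = [a for a in amplitudes if a > threshold]
    return {"mage": float(np.mean(qualifying)) if qualifying else None}


def day_to_day(trace: GlucoseTrace,
               tolerance_s: float = 150.0) -> dict[str, float | None]:
    """MODD and CONGA24 from samples pairable across a 24-hour lag.

    Clock times match within ``tolerance_s`` seconds (default +/-2.5 min,
    half a 5-minute CGM interval). Both need >= 2 days and at least one
    pairable time; CONGA24 additionally needs >= 2 pairs for its SD.
    """
    if trace.n_days < 2:
        return {"modd": None, "conga24": None}
    now = pd.DataFrame({"t": trace.index, "g": trace.values})
    earlier = now.copy()
    earlier["t"] = earlier["t"] + pd.Timedelta(hours=24)
    paired = pd.merge_asof(now, earlier, on="t", direction="nearest",
                           tolerance=pd.Timedelta(seconds=tolerance_s),
                           suffixes=("", "_prev")).dropna()
    if paired.empty:
        return {"modd": None, "conga24": None}
    diffs = (paired["g"] - paired["g_prev"]).to_numpy()
    return {
        "modd": float(np.mean(np.abs(diffs))),
        "conga24": _sd(diffs) if len(diffs) >= 2 else None,
    }


def hba1c_estimates(trace: GlucoseTrace) -> dict[str, float]:
    """Glucose management indicator and estimated A1c, both percent."""
    mean_g = float(np.mean(trace.values))
    return {
        "gmi_pct": 3.31 + 0.02392 * mean_g,
        "ea1c_pct": (mean_g + 46.7) / 28.7,
    }


_ABSENT_REASONS = {
    "intraday_sd_mean": "needs >= 2 days each with >= 2 samples",
    "intraday_sd_median": "needs >= 2 days each with >= 2 samples",
    "intraday_sd_sd": "needs >= 2 days each with >= 2 samples",
    "intraday_cv_mean": "needs >= 2 days each with >= 2 samples",
    "intraday_cv_median": "needs >= 2 days each with >= 2 samples",
    "intraday_cv_sd": "needs >= 2 days each with >= 2 samples",
    "mean_in_range": "no samples inside the target range",
    "mean_out_range": "no samples outside the target range",
    "adrr": "needs >= 2 days",
    "mage": "no excursion exceeds the SD threshold",
    "modd": "needs >= 2 days with pairable clock times",
    "conga24": "needs >= 2 days with >= 2 pairable clock times",
}


def compute_all_metrics(trace: GlucoseTrace,
                        range_config: RangeConfig | None = None,
                        mage_sd_multiplier: float = 1.0) -> MetricReport:
    """All 28 catalog metrics; unmet preconditions become absent-with-reason."""
    raw: dict[str, float | None] = {}
    raw.update(basic_stats(trace))
    raw.update(variability_stats(trace))
    raw.update(range_stats(trace, range_config))
    raw.update(risk_indices(trace))
    raw.update(mage(trace, mage_sd_multiplier))
    raw.update(day_to_day(trace))
    raw.update(hba1c_estimates(trace))
    metrics: dict[str, MetricValue] = {}
    for name, units in METRIC_CATALOG.items():
        value = raw[name]
        if value is None:
            metrics[name] = MetricValue(None, units, present=False,
                                        reason=_ABSENT_REASONS.get(name, "unavailable"))
        else:
            metrics[name] = MetricValue(float(value), units)
    return MetricReport(metrics, n_days=trace.n_days, n_samples=len(trace.values))


def lowess_trend(trace: GlucoseTrace, frac: float = 0.15) -> pd.Series:
    """LOWESS-smoothed glucose trend evaluated at the input time points."""
    if not 0 < frac <= 1:
        raise ContractError("frac must be in (0, 1]")
    if len(trace.values) < 10:
        raise DegenerateSmoothingError(
            f"LOWESS needs >= 10 samples; got {len(trace.values)}")
    t = (trace.index - trace.index[0]).total_seconds().to_numpy()
    fitted = _sm_lowess(trace.values, t, frac=frac, return_sorted=False)
    return pd.Series(fitted, index=trace.index, name="glucose_trend")


def plot_trend(trace: GlucoseTrace, trend: pd.Series, path) -> None:
    """Write a PNG of raw glucose points with the LOWESS trend overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(trace.index, trace.values, ".", ms=2, alpha=0.4, label="glucose")
    ax.plot(trend.index, trend.values, "-", lw=2, label="LOWESS trend")
    ax.set_xlabel("time")
    ax.set_ylabel("glucose (mg/dL)")
    ax.legend()
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
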