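"""Resting heart rate (RHR) from wearable heart-rate and step-count data.

RHR is estimated as the median of an optimally chosen low-activity subset
of the heart-rate series. A minute belongs to the candidate subset for
parameters (n, m) when the rolling sum of steps over the trailing half-open
window ``(t - m min, t]`` is at most ``n``. The pair (n, m) is chosen by
exhaustive grid search minimizing a standard-deviation penalty::

    P(n, m) = SD(subset) + lambda * SD(all HR) * shortfall(subset)

where ``shortfall = max(0, min_fraction*N - |subset|) / (min_fraction*N)``
is the relative deficit below the minimum admissible subset size. Minimizing
subset SD alone would collapse onto near-empty subsets; the shortfall term
keeps the optimum a low-variation subset that still represents the data.
Subsets that are empty, or that touch fewer than ``min_days`` distinct
calendar days, are disqualified outright (infinite penalty).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, EmptyInputError, NoRestingDataError
from .timeseries_io import (BioSeries, Channel, align_series, default_bounds,
                            read_series, validate_series)

logger = logging.getLogger(__name__)

__all__ = ["RHRSearchConfig", "RHREstimate", "rolling_step_sum",
           "low_activity_subset", "penalty", "search_rhr", "estimate_rhr"]

_DEFAULT_N_GRID = tuple(range(0, 11)) + tuple(range(15, 51, 5))
_DEFAULT_M_GRID = tuple(range(5, 61, 5))


@dataclass(frozen=True)
class RHRSearchConfig:
    """Grid and penalty settings for the (n, m) search.

    ``n_grid`` are step-count thresholds, ``m_grid`` rolling-window lengths
    in minutes; ``lambda_`` weighs the coverage-shortfall term;
    ``min_fraction`` is the minimum admissible subset size as a fraction of
    all heart-rate samples; ``min_days`` is the number of distinct calendar
    days a subset must touch (``None`` = 3 when the recording spans >= 3
    days, else the span itself).
    """

    n_grid: tuple[int, ...] = _DEFAULT_N_GRID
    m_grid: tuple[int, ...] = _DEFAULT_M_GRID
    lambda_: float = 1.0
    min_fraction: float = 0.10
    min_days: int | None = None

    def __post_init__(self) -> None:
        for name, grid in (("n_grid", self.n_grid), ("m_grid", self.m_grid)):
            if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
                raise ContractError(f"{name} must be non-empty and strictly increasing")
        if self.lambda_ < 0:
            raise ContractError("lambda_ must be >= 0")
        if not 0 < self.min_fraction <= 1:
            raise ContractError("min_fraction must be in (0, 1]")
        if self.min_days is not None and self.min_days < 1:
            raise ContractError("min_days must be >= 1")

    def resolved_min_days(self, span_days: int) -> int:
        if self.min_days is not None:
            return self.min_days
        return 3 if span_days >= 3 else max(1, span_days)


@dataclass(frozen=True)
class RHREstimate:
    """Result of the RHR search: the estimate plus full diagnostics."""

    rhr: float
    n_star: int
    m_star: int
    subset_size: int
    penalty_value: float
    per_day_medians: dict
    search_table: pd.DataFrame  # columns n, m, subset_size, subset_sd, penalty

    def to_dict(self) -> dict:
        return {
            "rhr": self.rhr,
            "n_star": self.n_star,
            "m_star": self.m_star,
            "subset_size": self.subset_size,
            "penalty_value": self.penalty_value,
            "per_day_medians": {str(k): v for k, v in self.per_day_medians.items()},
        }


def _sd(values: np.ndarray) -> float:
    """Sample SD (n-1 denominator); 0 for fewer than 2 values."""
    return float(np.std(values, ddof=1)) if len(values) >= 2 else 0.0


def rolling_step_sum(steps: BioSeries, m: int) -> BioSeries:
    """Rolling sum of steps over the trailing half-open window ``(t - m, t]``.

    ``steps`` must be on a 1-minute grid (zero-filled); the first ``m - 1``
    minutes use the partial window available so far.
    """
    if not len(steps):
        raise EmptyInputError("rolling step sum of an empty series")
    if m < 1:
        raise ContractError("window length m must be >= 1 minute")
    sums = steps.data.rolling(window=m, min_periods=1).sum()
    return steps.with_data(sums)


def low_activity_subset(hr: BioSeries, steps: BioSeries, n: float, m: int) -> BioSeries:
    """Heart-rate samples at minutes whose trailing m-minute step sum <= n.

    ``hr`` and ``steps`` must already share a 1-minute grid (see
    :func:`dbdp.timeseries_io.align_series`).
    """
    common = hr.index.intersection(steps.index)
    if not len(common):
        raise EmptyInputError("heart-rate and step series do not overlap")
    sums = rolling_step_sum(steps.with_data(steps.data.loc[common]), m)
    keep = sums.data <= n
    return hr.with_data(hr.data.loc[common][keep.to_numpy()])


def penalty(hr_full: BioSeries, subset: BioSeries, config: RHRSearchConfig) -> float:
    """Standard-deviation penalty of a candidate low-activity subset."""
    if not len(hr_full):
        raise EmptyInputError("penalty needs a non-empty full heart-rate series")
    min_days = config.resolved_min_days(hr_full.span_days)
    if not len(subset) or subset.span_days < min_days:
        return math.inf
    floor = config.min_fraction * len(hr_full)
    shortfall = max(0.0, floor - len(subset)) / floor
    return _sd(subset.values) + config.lambda_ * _sd(hr_full.values) * shortfall


def search_rhr(hr: BioSeries, steps: BioSeries,
               config: RHRSearchConfig | None = None) -> RHREstimate:
    """Exhaustive (n, m) grid search; RHR = median of the optimal subset.

    Requires >= 1 full day of overlapping heart-rate and step data on a
    shared 1-minute grid. Ties are broken toward smaller m, then smaller n
    (the stricter rest definition).
    """
    config = config or RHRSearchConfig()
    common = hr.index.intersection(steps.index)
    if len(common) < 1440:
        raise EmptyInputError(
            f"need >= 1 full day (1440 min) of overlapping HR and steps; got {len(common)}")
    hr_v = hr.data.loc[common].to_numpy(dtype=float)
    steps_s = steps.data.loc[common]
    dates = common.normalize()
    date_codes = pd.factorize(dates)[0]
    n_total = len(hr_v)
    span_days = int(dates.nunique())
    min_days = config.resolved_min_days(span_days)
    full_sd = _sd(hr_v)
    floor = config.min_fraction * n_total

    rows = []
    best = None  # (penalty, m, n, mask)
    for m in config.m_grid:
        sums = steps_s.rolling(window=m, min_periods=1).sum().to_numpy()
        for n in config.n_grid:
            mask = sums <= n
            size = int(mask.sum())
            if size == 0 or len(np.unique(date_codes[mask])) < min_days:
                sd = math.nan
                pen = math.inf
            else:
                sd = _sd(hr_v[mask])
                shortfall = max(0.0, floor - size) / floor
                pen = sd + config.lambda_ * full_sd * shortfall
            rows.append((n, m, size, sd, pen))
            if math.isfinite(pen) and (best is None or pen < best[0]):
                best = (pen, m, n, mask)

    table = pd.DataFrame(rows, columns=["n", "m", "subset_size", "subset_sd", "penalty"])
    if best is None:
        raise NoRestingDataError(
            "every (n, m) candidate was disqualified: no subset is non-empty and "
            f"touches >= {min_days} distinct day(s); tightest constraint is "
            f"min_days={min_days}")
    pen, m_star, n_star, mask = best
    subset = pd.Series(hr_v[mask], index=common[mask])
    per_day = {d.date(): float(v) for d, v in subset.groupby(subset.index.normalize()).median().items()}
    logger.info("search_rhr: optimum n=%d m=%d subset=%d/%d penalty=%.3f",
                n_star, m_star, len(subset), n_total, pen)
    return RHREstimate(
        rhr=float(subset.median()),
        n_star=int(n_star),
        m_star=int(m_star),
        subset_size=int(mask.sum()),
        penalty_value=float(pen),
        per_day_medians=per_day,
        search_table=table,
    )


def estimate_rhr(hr_path, steps_path, config: RHRSearchConfig | None = None,
                 out_json=None, time_column: str = "Time",
                 value_column: str = "Value", timezone: str | None = None) -> RHREstimate:
    """File-level orchestration: read -> validate -> resample/align -> search."""
    hr = read_series(hr_path, Channel.HEART_RATE, time_column, value_column, timezone)
    steps = read_series(steps_path, Channel.STEPS, time_column, value_column, timezone)
    hr, hr_rej = validate_series(hr, default_bounds(Channel.HEART_RATE))
    steps, st_rej = validate_series(steps, default_bounds(Channel.STEPS))
    if hr.nominal_interval != 60 or steps.nominal_interval != 60:
        logger.warning("estimate_rhr: resampling native data onto the 1-minute grid")
    paired = align_series(hr, steps, 60.0)
    hr_g = BioSeries(Channel.HEART_RATE, paired[Channel.HEART_RATE.value], 60.0, hr.subject_id)
    steps_g = BioSeries(Channel.STEPS, paired[Channel.STEPS.value], 60.0, steps.subject_id)
    estimate = search_rhr(hr_g, steps_g, config)
    if out_json is not None:
        payload = estimate.to_dict()
        payload["rejected_samples"] = {"heart_rate": hr_rej, "steps": st_rej}
        with open(out_json, "w") as fh:
            json.dump(payload, fh, indent=2)
    return estimate
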