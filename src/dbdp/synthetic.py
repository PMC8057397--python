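"""Ground-truth-bearing simulators for every pipeline.

The generators emulate the structure the estimators exploit, with the truth
recorded alongside:

* :func:`simulate_hr_steps` — a minute-grid heart-rate/step pair with a
  known resting heart rate, a single 24-hour circadian sinusoid (trough
  entrained to the middle of the sleep window), sleep-time HR depression,
  scheduled activity bouts that raise HR and emit steps, and i.i.d.
  Gaussian sensor noise;
* :func:`simulate_cgm` — a 5-minute-grid glucose trace of baseline plus
  per-meal excursion kernels (linear rise, exponential decay) and Gaussian
  noise, with noiseless closed-form expectations recorded;
* :func:`degrade_missing` — removes a known fraction of grid slots
  (uniformly at random or as one contiguous block) and returns the exact
  removed-slot mask.

All generators are pure functions of their parameters (seed included):
repeat calls are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cgm import GlucoseTrace
from .errors import ContractError
from .timeseries_io import BioSeries, Channel

__all__ = ["HRSimParams", "CGMSimParams", "GroundTruth", "daily_bouts",
           "exercise_only_bouts", "simulate_hr_steps", "simulate_cgm",
           "degrade_missing"]

#: Fixed simulation start (a Monday at local midnight).
SIM_START = pd.Timestamp("2021-01-04 00:00:00")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows that the estimators must recover."""

    rhr_true: float | None = None
    sleep_intervals: tuple = ()
    missing_mask: tuple = ()
    cgm_expected: dict = field(default_factory=dict)


def daily_bouts(days: int, sleep_window: tuple[float, float] = (23.0, 7.0),
                exercise_offsets_h: tuple[float, ...] = (1.5, 5.5, 11.0),
                duration_min: int = 30, steps_per_min: float = 80.0,
                hr_rise: float = 40.0,
                walk_every_min: float | None = 45.0, walk_duration_min: int = 3,
                walk_steps_per_min: float = 40.0, walk_hr_rise: float = 8.0
                ) -> tuple[tuple[float, int, float, float], ...]:
    """A standard free-living activity schedule repeated each day.

    Activity is anchored to the wake period implied by ``sleep_window`` (a
    shift worker's day follows their schedule, not the clock): a few
    sustained exercise bouts at fixed offsets after wake-up, plus short
    low-intensity walks every ``walk_every_min`` minutes throughout waking
    hours — step counters register movement all day, not only during
    workouts. Returns (start_minute_from_sim_start, duration_min,
    steps_per_min, hr_rise) tuples, the format :class:`HRSimParams`
    expects, clipped to the simulated span.
    """
    span_min = days * 1440.0
    sleep_start, sleep_end = sleep_window
    wake_start_h = sleep_end % 24
    wake_len_h = 24.0 - ((sleep_end - sleep_start) % 24 or 24)

    raw: list[tuple[float, int, float, float]] = []
    for day in range(-1, days):
        wake0 = day * 1440.0 + wake_start_h * 60.0
        exercise = []
        for off_h in exercise_offsets_h:
            start = wake0 + off_h * 60.0
            if off_h * 60.0 + duration_min <= wake_len_h * 60.0:
                exercise.append((start, duration_min))
                raw.append((start, duration_min, steps_per_min, hr_rise))
        walk_off = 0.0
        while (walk_every_min is not None
               and walk_off + walk_duration_min <= wake_len_h * 60.0):
            start = wake0 + walk_off
            overlaps = any(s - walk_duration_min < start < s + d
                           for s, d in exercise)
            if not overlaps:
                raw.append((start, walk_duration_min,
                            walk_steps_per_min, walk_hr_rise))
            walk_off += walk_every_min

    bouts = []
    for start, dur, rate, rise in sorted(raw):
        end = start + dur
        start_clip, end_clip = max(start, 0.0), min(end, span_min)
        if end_clip - start_clip >= 1:
            bouts.append((start_clip, int(end_clip - start_clip), rate, rise))
    return tuple(bouts)


def exercise_only_bouts(days: int, sleep_window: tuple[float, float] = (23.0, 7.0),
                        **kwargs) -> tuple[tuple[float, int, float, float], ...]:
    """Sustained exercise bouts only, no scattered walks.

    The schedule used by the resting-heart-rate recovery experiments:
    steps appear only during workouts that visibly raise heart rate, so
    sedentary wakefulness leaves long zero-step stretches. Accepts the same
    keyword arguments as :func:`daily_bouts` (minus the walk settings).
    """
    return daily_bouts(days, sleep_window=sleep_window, walk_every_min=None,
                       **kwargs)


@dataclass(frozen=True)
class HRSimParams:
    """Heart-rate/step simulation parameters.

    ``rhr_true`` is the wakeful-rest heart rate the estimator should
    recover. ``sleep_windows`` are (start_hour, end_hour) wall-clock pairs
    repeated daily (wrapping midnight allowed). ``bout_schedule`` entries
    are (start_minute, duration_min, steps_per_min, hr_rise).
    ``circadian_trough_h`` defaults to the midpoint of the first sleep
    window (entrained circadian phase).
    """

    rhr_true: float = 60.0
    circadian_amp: float = 3.0
    sleep_windows: tuple[tuple[float, float], ...] = ((23.0, 7.0),)
    sleep_drop: float = 5.0
    bout_schedule: tuple[tuple[float, int, float, float], ...] | None = None
    noise_sd: float = 3.0
    days: int = 7
    seed: int = 0
    circadian_trough_h: float | None = None

    def __post_init__(self) -> None:
        if self.rhr_true <= 0:
            raise ContractError("rhr_true must be > 0")
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be >= 0")
        if self.days < 1:
            raise ContractError("days must be >= 1")
        if self.sleep_drop >= self.rhr_true:
            raise ContractError("sleep_drop must stay below rhr_true (safe range)")

    def resolved_bouts(self) -> tuple[tuple[float, int, float, float], ...]:
        if self.bout_schedule is not None:
            return self.bout_schedule
        window = self.sleep_windows[0] if self.sleep_windows else (23.0, 7.0)
        return daily_bouts(self.days, sleep_window=window)

    def resolved_trough(self) -> float:
        if self.circadian_trough_h is not None:
            return self.circadian_trough_h
        if not self.sleep_windows:
            return 3.0
        start, end = self.sleep_windows[0]
        length = (end - start) % 24 or 24
        return (start + length / 2.0) % 24


def _sleep_mask(minutes_of_day: np.ndarray,
                windows: tuple[tuple[float, float], ...]) -> np.ndarray:
    mask = np.zeros(len(minutes_of_day), dtype=bool)
    for start_h, end_h in windows:
        s, e = start_h * 60.0, end_h * 60.0
        if s <= e:
            mask |= (minutes_of_day >= s) & (minutes_of_day < e)
        else:  # wraps midnight
            mask |= (minutes_of_day >= s) | (minutes_of_day < e)
    return mask


def _sleep_intervals(params: HRSimParams) -> tuple[tuple[pd.Timestamp, pd.Timestamp], ...]:
    """Absolute sleep intervals implied by the daily windows, clipped to span."""
    span_end = SIM_START + pd.Timedelta(minutes=params.days * 1440)
    intervals = []
    for start_h, end_h in params.sleep_windows:
        length_h = (end_h - start_h) % 24 or 24
        # nightly instances, including one starting the day before the span
        for day in range(-1, params.days):
            start = SIM_START + pd.Timedelta(hours=24 * day + start_h)
            end = start + pd.Timedelta(hours=length_h)
            start, end = max(start, SIM_START), min(end, span_end)
            if end > start:
                intervals.append((start, end))
    return tuple(sorted(intervals))


def simulate_hr_steps(params: HRSimParams | None = None
                      ) -> tuple[BioSeries, BioSeries, GroundTruth]:
    """Simulate paired heart-rate and step series on the 1-minute grid.

    HR(t) = rhr_true + circadian term - sleep_drop inside sleep windows
    + hr_rise inside bouts + Gaussian noise; steps are zero except inside
    bouts. Overlapping bouts are a contract error.
    """
    params = params or HRSimParams()
    n = params.days * 1440
    index = pd.date_range(SIM_START, periods=n, freq="min")
    minutes = np.arange(n, dtype=float)
    minutes_of_day = minutes % 1440.0

    trough = params.resolved_trough()
    hours_of_day = minutes_of_day / 60.0
    circadian = -params.circadian_amp * np.cos(2 * np.pi * (hours_of_day - trough) / 24.0)

    hr = np.full(n, params.rhr_true, dtype=float) + circadian
    asleep = _sleep_mask(minutes_of_day, params.sleep_windows)
    hr[asleep] -= params.sleep_drop

    steps = np.zeros(n, dtype=float)
    in_bout = np.zeros(n, dtype=bool)
    for start_min, duration, rate, rise in params.resolved_bouts():
        i0, i1 = int(start_min), int(start_min) + int(duration)
        if i0 < 0 or i1 > n:
            raise ContractError("bout outside the simulated span")
        if in_bout[i0:i1].any():
            raise ContractError("overlapping bouts in bout_schedule")
        in_bout[i0:i1] = True
        steps[i0:i1] = rate
        hr[i0:i1] += rise

    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        hr = hr + rng.normal(0.0, params.noise_sd, size=n)

    truth = GroundTruth(rhr_true=params.rhr_true,
                        sleep_intervals=_sleep_intervals(params))
    hr_series = BioSeries(Channel.HEART_RATE, pd.Series(hr, index=index), 60.0, "sim")
    steps_series = BioSeries(Channel.STEPS, pd.Series(steps, index=index), 60.0, "sim")
    return hr_series, steps_series, truth


@dataclass(frozen=True)
class CGMSimParams:
    """CGM simulation parameters: baseline plus daily meal excursions.

    Each meal contributes a kernel rising linearly to ``excursion_amp`` over
    ``rise_min`` minutes, then decaying exponentially with time constant
    ``decay_min`` minutes.
    """

    baseline: float = 100.0
    meal_times: tuple[float, ...] = (8.0, 13.0, 19.0)
    excursion_amp: float = 80.0
    rise_min: float = 30.0
    decay_min: float = 60.0
    noise_sd: float = 5.0
    days: int = 14
    interval_s: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not 20 <= self.baseline <= 600:
            raise ContractError("baseline must lie within plausibility bounds")
        if self.excursion_amp < 0 or self.noise_sd < 0:
            raise ContractError("amplitudes must be >= 0")
        if self.days < 1 or self.interval_s <= 0:
            raise ContractError("days >= 1 and interval_s > 0 required")


def _meal_kernel(minutes_since_meal: np.ndarray, amp: float,
                 rise: float, decay: float) -> np.ndarray:
    t = minutes_since_meal
    out = np.zeros_like(t)
    rising = (t >= 0) & (t < rise)
    out[rising] = amp * t[rising] / rise
    decaying = t >= rise
    out[decaying] = amp * np.exp(-(t[decaying] - rise) / decay)
    return out


def simulate_cgm(params: CGMSimParams | None = None
                 ) -> tuple[GlucoseTrace, GroundTruth]:
    """Simulate a CGM trace; noiseless closed-form expectations in truth."""
    params = params or CGMSimParams()
    per_day = int(round(86400 / params.interval_s))
    n = params.days * per_day
    index = pd.date_range(SIM_START, periods=n, freq=f"{params.interval_s}s")
    minutes = (index - SIM_START).total_seconds().to_numpy() / 60.0

    noiseless = np.full(n, params.baseline, dtype=float)
    for day in range(params.days):
        for meal_h in params.meal_times:
            meal_min = day * 1440.0 + meal_h * 60.0
            noiseless += _meal_kernel(minutes - meal_min, params.excursion_amp,
                                      params.rise_min, params.decay_min)

    rng = np.random.default_rng(params.seed)
    glucose = noiseless + (rng.normal(0.0, params.noise_sd, size=n)
                           if params.noise_sd > 0 else 0.0)

    in_range = (noiseless >= 70.0) & (noiseless <= 180.0)
    truth = GroundTruth(cgm_expected={
        "noiseless_mean": float(np.mean(noiseless)),
        "noiseless_tir_pct_70_180": 100.0 * float(np.mean(in_range)),
        "noiseless_min": float(np.min(noiseless)),
        "noiseless_max": float(np.max(noiseless)),
    })
    trace = GlucoseTrace(BioSeries(Channel.GLUCOSE, pd.Series(glucose, index=index),
                                   float(params.interval_s), "sim"))
    return trace, truth


def degrade_missing(series: BioSeries, pattern: str = "random",
                    fraction: float = 0.0, seed: int = 0
                    ) -> tuple[BioSeries, pd.DatetimeIndex]:
    """Remove a known fraction of samples; return series + removed-slot mask.

    ``random`` removes ``floor(fraction * n)`` slots uniformly without
    replacement; ``block`` removes one contiguous run of that length at a
    seeded random offset. ``fraction`` must lie in [0, 1).
    """
    if not 0 <= fraction < 1:
        raise ContractError("fraction must be in [0, 1)")
    if pattern not in ("random", "block"):
        raise ContractError("pattern must be 'random' or 'block'")
    n = len(series)
    k = int(np.floor(fraction * n))
    if k == 0:
        return series, pd.DatetimeIndex([])
    rng = np.random.default_rng(seed)
    if pattern == "random":
        removed_pos = np.sort(rng.choice(n, size=k, replace=False))
    else:
        start = int(rng.integers(0, n - k + 1))
        removed_pos = np.arange(start, start + k)
    mask = series.index[removed_pos]
    keep = np.ones(n, dtype=bool)
    keep[removed_pos] = False
    return series.with_data(series.data[keep]), mask
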