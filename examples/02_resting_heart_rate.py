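"""Estimate resting heart rate from paired heart-rate and step series.

Simulates a week of wearable data for a subject whose true wakeful-rest
heart rate is 63 bpm (workouts raise HR by ~40 bpm and emit steps), then
runs the (n, m) penalty search: n is the largest rolling step sum a
"resting" minute may have in its trailing m-minute window, and the
estimate is the median heart rate of the optimal low-activity subset.
"""

from dbdp.rhr import search_rhr
from dbdp.synthetic import HRSimParams, exercise_only_bouts, simulate_hr_steps

params = HRSimParams(rhr_true=63.0, seed=11, bout_schedule=exercise_only_bouts(7))
hr, steps, truth = simulate_hr_steps(params)

estimate = search_rhr(hr, steps)
print(f"true resting heart rate : {truth.rhr_true:.1f} bpm")
print(f"estimated               : {estimate.rhr:.1f} bpm")
print(f"optimal parameters      : n*={estimate.n_star} steps, "
      f"m*={estimate.m_star} min")
print(f"subset size             : {estimate.subset_size} of {len(hr)} minutes")
print(f"penalty at the optimum  : {estimate.penalty_value:.3f}")

print("\nper-day medians of the optimal subset (bpm):")
for date, median in estimate.per_day_medians.items():
    print(f"  {date}: {median:.1f}")
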