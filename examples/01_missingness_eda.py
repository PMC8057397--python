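"""Quantify wearable data completeness per day and per hour.

Simulates a 3-day heart-rate recording, knocks out 30% of the minutes in
one contiguous block (a dead battery, say), and summarizes what fraction
of each hour's expected samples actually arrived.
"""

from dbdp.eda import missingness_by_day_hour
from dbdp.synthetic import HRSimParams, degrade_missing, simulate_hr_steps

hr, _, _ = simulate_hr_steps(HRSimParams(days=3, seed=0))
degraded, mask = degrade_missing(hr, pattern="block", fraction=0.3, seed=0)
print(f"removed {len(mask)} of {len(hr)} minute samples "
      f"({mask[0]} .. {mask[-1]})")

summary = missingness_by_day_hour(degraded, nominal_interval=60)
print("\nfraction of expected samples present, per day:")
for date, fraction in summary.per_day.items():
    print(f"  {date}: {fraction:.3f}")

# hours fully inside the removed block read 0.0; untouched hours read 1.0
grid = summary.heat_grid()
print("\nday x hour heat grid (rows = days, columns = hours 0-23):")
print(grid.round(2).to_string())
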