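"""Daily soil temperature/moisture metrics on a simulated season.

Generates a five-week virtual season for four mulching treatments,
aggregates the sensor streams to daily metrics, and attaches Duncan
letters to the treatment means (days as replicates).
"""

from soilmulch import ScenarioConfig, daily_summaries, generate, group_summary
from soilmulch.timeseries import metric_replicates

cfg = ScenarioConfig(start="2021-01-01", end="2021-02-05", interval="30min",
                     irrigation_times=("2021-01-08 10:00", "2021-01-20 10:00",
                                       "2021-02-01 10:00"), seed=42)
exp = generate(cfg)
daily = daily_summaries(exp.sensors)

print("period means of the daily metrics:")
print(daily.groupby("treatment")[["DMnT", "DMT", "DMxT", "DTR", "DMSM"]]
      .mean().round(2))

print("\nDuncan letters for the daily temperature range (DTR):")
print(group_summary(metric_replicates(daily, "DTR")).to_string(index=False))
# Bare soil shows the widest daily swing; every mulch damps it, and the
# letters say which damping differences are statistically real.
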