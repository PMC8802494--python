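"""Run the eleven-test battery on a trial with crossing survival curves.

Simulates a two-arm trial in which the experimental arm does worse early
and better late (survival curves cross at t = 1.5), then applies the full
battery. Expect the log-rank test to miss the difference while several
omnibus tests (mdir, MaxCombo, KONP, ABC) flag it: under crossing hazards
the early and late hazard differences cancel in the log-rank sum.
"""

import numpy as np

from crosshaz import BatteryConfig, battery_table, preset, run_battery, simulate_sample

spec = preset("crossing-1", n_per_arm=300)
sample = simulate_sample(spec, rng=np.random.default_rng(12))

config = BatteryConfig(alpha=0.05, n_resamples=5000, seed=12)
results = run_battery(sample, config)
table = battery_table(results, alpha=config.alpha, n_resamples=config.n_resamples)

print(f"n = {sample.n} subjects, {int(sample.status.sum())} events")
print(table[["statistic", "p_value", "significant"]].round(4).to_string())
print("\np_value <= 0.05 means the test detects a survival difference; the"
      "\nlog-rank (LR) row typically stays above 0.05 here while omnibus"
      "\ntests reject — the motivating phenomenon for this battery.")
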