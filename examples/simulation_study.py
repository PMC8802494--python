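"""Type-I error and power comparison across hazard scenarios.

Runs a small Monte-Carlo study: under the null (identical arms) every test
should reject about 5% of the time; under crossing hazards the omnibus
tests should clearly outperform the log-rank. Scale the replicate counts
up for publication-quality tables.
"""

from crosshaz import ALL_TESTS, crossing_times, preset, rejection_study

TESTS = list(ALL_TESTS)

for name in ("null", "crossing-1"):
    spec = preset(name, n_per_arm=150)
    cross = crossing_times(spec.arm1, spec.arm2)
    label = f"scenario '{name}'" + (f" (curves cross at t={cross})" if cross else "")
    table = rejection_study(spec, TESTS, n_reps=100, alpha=0.05, seed=5,
                            n_resamples=500)
    print(f"\n{label}, n=150/arm, 100 replicates:")
    print(table[["rejection_rate", "se"]].round(3).to_string())

print("\nUnder 'null' every rate estimates the type-I error (target 0.05);"
      "\nunder 'crossing-1' the rates are power: LR should be the lowest,"
      "\nmdir/KONP/MaxCombo/ABC the highest.")
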