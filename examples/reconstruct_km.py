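"""Rebuild individual patient data from a published Kaplan-Meier figure.

Simulates a trial with a fixed data cutoff, pretends its KM curves were
published (exact digitized step coordinates + a number-at-risk table every
half time unit), reconstructs pseudo-IPD from those artifacts alone, and
compares the usual quality statistics — median survival per arm and the
Cox hazard ratio — between the original and reconstructed data.
"""

import dataclasses

import numpy as np

from crosshaz import (Censoring, cox_hr, kaplan_meier, median_survival,
                      preset, quality_report, simulate_sample)
from crosshaz.reconstruct import exact_digitization, reconstruct_ipd

spec = dataclasses.replace(preset("ph", n_per_arm=200),
                           censoring=Censoring("administrative", at=2.5))
original = simulate_sample(spec, rng=np.random.default_rng(7))

grid = np.arange(0.0, original.time.max() + 0.25, 0.5)
digitized = exact_digitization(original, grid)
recon = reconstruct_ipd(digitized)

print(f"reconstructed {recon.sample.n} subjects "
      f"(original {original.n}); max KM deviation "
      f"{recon.max_km_deviation:.4f}")

published = {
    "ms1": median_survival(kaplan_meier(*original.arm(1))),
    "ms2": median_survival(kaplan_meier(*original.arm(2))),
    "hr": cox_hr(original)[0],
}
report = quality_report(recon, {k: v for k, v in published.items() if v is not None})
print(report.round(4).to_string(index=False))
print("\n'published' = statistic of the original trial, 'reconstructed' ="
      "\nthe same statistic recomputed from the rebuilt IPD; small deviations"
      "\nmean the figure + risk table carry nearly all the information.")
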