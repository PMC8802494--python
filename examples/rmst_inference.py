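"""Restricted mean survival time: estimation and testing.

The RMST up to tau is the area under the survival curve on [0, tau] — the
expected event-free time in that window, a hazard-free effect measure that
remains interpretable when hazards are non-proportional. This example
estimates per-arm RMSTs and runs the asymptotic (RMST2), permutation
(RMST1) and combined Cox+RMST tests.
"""

import numpy as np

from crosshaz import (cox_rmst_test, preset, rmst, rmst1_test, rmst2_test,
                      simulate_sample, tau_rule)

sample = simulate_sample(preset("late", n_per_arm=250),
                         rng=np.random.default_rng(3))
tau = tau_rule(sample)  # 90% of the smaller arm-wise max follow-up
print(f"tau = {tau:.3f}")

for j in (1, 2):
    est = rmst(*sample.arm(j), tau)
    print(f"arm {j}: RMST = {est.estimate:.3f} "
          f"(SE {np.sqrt(est.variance):.3f})")

for res in (rmst2_test(sample, tau=tau),
            rmst1_test(sample, tau=tau, n_resamples=5000, seed=3),
            cox_rmst_test(sample, tau=tau, n_resamples=5000, seed=3)):
    print(f"{res.method:8s} p = {res.p_value:.4f}")

print("\nA significant RMST test says the mean event-free time up to tau"
      "\ndiffers between arms; here the hazard difference emerges late, a"
      "\nregime where RMST keeps interpretability but may trail omnibus"
      "\ntests in power.")
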