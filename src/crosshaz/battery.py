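"""Run the full battery of eleven two-sample survival tests on one dataset.

The battery mirrors the canonical comparison layout for crossing-hazards
methods: the log-rank (LR) and Peto–Peto (PP) references, the three RMST
tests (RMST1 resampling, RMST2 asymptotic, coxRMST combined), the two
sample-space-partition permutation tests (KONP_chi, KONP_llr), the
multiple-direction log-rank test (mdir), the two-stage procedure (2ST), the
area between curves (ABC) and the MaxCombo test.

Each test draws its randomness from a seed derived deterministically from
the master seed and the method name, so adding or removing a test never
changes another test's p-value.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import pandas as pd

from .combine import maxcombo_test, mdir_test
from .core import SurvivalSample
from .omnibus import abc_test, konp_test, two_stage_test
from .results import TestResult
from .rmst import cox_rmst_test, rmst1_test, rmst2_test
from .wlr import logrank_test, peto_peto_test

__all__ = ["BatteryConfig", "ALL_TESTS", "run_battery", "run_single",
           "derive_seed", "battery_table"]

#: Battery column order.
ALL_TESTS = ("LR", "PP", "RMST1", "RMST2", "coxRMST", "KONP_chi",
             "KONP_llr", "mdir", "2ST", "ABC", "MaxCombo")


def derive_seed(master: int | None, method: str) -> int:
    """Stable per-test seed: master seed xor CRC32 of the method name."""
    base = 0 if master is None else int(master)
    return (base * 2654435761 + zlib.crc32(method.encode())) % (2**31 - 1)


@dataclass(frozen=True)
class BatteryConfig:
    alpha: float = 0.05
    n_resamples: int = 5000
    seed: int | None = None
    tau: float | None = None          # None -> tau_rule
    tests: tuple = ALL_TESTS

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_resamples < 100:
            raise ValueError("n_resamples must be >= 100")
        unknown = set(self.tests) - set(ALL_TESTS)
        if unknown:
            raise ValueError(f"unknown tests: {sorted(unknown)}")


def run_single(sample: SurvivalSample, method: str, seed: int | None = None,
               n_resamples: int = 5000, alpha: float = 0.05,
               tau: float | None = None) -> TestResult:
    """Run one named battery test with its own seed."""
    B = n_resamples
    if method == "LR":
        return logrank_test(sample)
    if method == "PP":
        return peto_peto_test(sample)
    if method == "RMST1":
        return rmst1_test(sample, tau=tau, n_resamples=B, seed=seed)
    if method == "RMST2":
        return rmst2_test(sample, tau=tau)
    if method == "coxRMST":
        return cox_rmst_test(sample, tau=tau, n_resamples=B, seed=seed)
    if method == "KONP_chi":
        return konp_test(sample, variant="chi", n_perm=B, seed=seed)
    if method == "KONP_llr":
        return konp_test(sample, variant="llr", n_perm=B, seed=seed)
    if method == "mdir":
        r = mdir_test(sample, n_perm=B, seed=seed)
        return TestResult("mdir", r.statistic, r.p_value, dict(r.metadata))
    if method == "2ST":
        return two_stage_test(sample, alpha=alpha, n_boot=B, seed=seed)
    if method == "ABC":
        return abc_test(sample, n_perm=B, seed=seed)
    if method == "MaxCombo":
        r = maxcombo_test(sample, n_resamples=B, seed=seed)
        return TestResult("MaxCombo", r.statistic, r.p_value, dict(r.metadata))
    raise ValueError(f"unknown test {method!r}")


def run_battery(sample: SurvivalSample,
                config: BatteryConfig | None = None) -> list[TestResult]:
    """Run the selected tests; failures are reported as NA results, the row
    is never aborted."""
    config = config or BatteryConfig()
    results = []
    for method in config.tests:
        seed = derive_seed(config.seed, method)
        try:
            res = run_single(sample, method, seed=seed,
                             n_resamples=config.n_resamples,
                             alpha=config.alpha, tau=config.tau)
        except Exception as exc:  # per-test failure -> NA entry
            res = TestResult(method, float("nan"), float("nan"),
                             {"error": str(exc)})
        results.append(res)
    return results


def battery_table(results: list[TestResult], alpha: float = 0.05,
                  n_resamples: int = 5000) -> pd.DataFrame:
    """Render battery results as a one-row-per-test table.

    Printed p-values are floored at 1/(n_resamples + 1) so a resampling
    p-value is never rendered as exactly zero.
    """
    floor = 1.0 / (n_resamples + 1)
    rows = []
    for r in results:
        p = r.p_value
        rows.append({
            "test": r.method,
            "statistic": r.statistic,
            "p_value": p if p != p else max(p, floor),
            "significant": bool(p <= alpha) if p == p else False,
            "note": r.metadata.get("error", ""),
        })
    return pd.DataFrame(rows).set_index("test")
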