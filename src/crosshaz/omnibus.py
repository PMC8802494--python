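"""Omnibus tests for survival differences of unspecified shape.

* ``konp_test`` — sample-space-partition permutation tests: at every pooled
  event time the sample is cross-classified into a 2x2 table of
  arm x {failed by t, survived past t}, with subjects censored before t
  allocated fractionally through the arm-wise Kaplan–Meier estimate; the
  Pearson chi-square ("chi") or likelihood-ratio ("llr") contributions are
  summed over event times and calibrated by group-label permutation.
* ``abc_test`` — the integrated L1 distance between the two KM curves (the
  area between curves), permutation-calibrated.
* ``two_stage_test`` — a two-stage procedure: stage 1 is the log-rank test
  at a fraction of alpha; if it fails to reject, stage 2 applies a
  data-driven sign-change (crossing) weight and is permutation-calibrated,
  so the overall size stays at or below alpha.
"""

from __future__ import annotations

import numpy as np

from ._perm import PermutationEngine
from .core import SurvivalSample
from .results import TestResult
from .wlr import logrank_test

__all__ = ["konp_test", "abc_test", "two_stage_test"]


def _konp_statistics(engine: PermutationEngine, n1: int, n2: int,
                     variant: str) -> np.ndarray:
    """Per-replicate KONP statistic summed over pooled event times."""
    ev = engine.event_mask
    S1, S2 = engine.group_km()
    S1, S2 = S1[:, ev], S2[:, ev]
    n = float(n1 + n2)
    O = np.stack([n1 * (1.0 - S1), n1 * S1,          # arm1: failed, survived
                  n2 * (1.0 - S2), n2 * S2])          # arm2: failed, survived
    col_f = O[0] + O[2]
    col_s = O[1] + O[3]
    E = np.stack([n1 * col_f / n, n1 * col_s / n,
                  n2 * col_f / n, n2 * col_s / n])
    valid = (col_f > 1e-12) & (col_s > 1e-12)  # degenerate tables contribute 0
    if variant == "chi":
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(E > 0, (O - E) ** 2 / np.maximum(E, 1e-300), 0.0)
        per_time = contrib.sum(axis=0)
    else:  # likelihood-ratio type, 0 log 0 = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((O > 0) & (E > 0), O / np.maximum(E, 1e-300), 1.0)
            contrib = O * np.log(ratio)
        per_time = 2.0 * contrib.sum(axis=0)
    per_time = np.where(valid, per_time, 0.0)
    return per_time.sum(axis=1)


def konp_test(sample: SurvivalSample, variant: str = "chi",
              n_perm: int = 5000, seed: int | None = None,
              exact: bool = False) -> TestResult:
    """Sample-space-partition permutation test (Pearson or LLR variant)."""
    if variant not in ("chi", "llr"):
        raise ValueError("variant must be 'chi' or 'llr'")
    engine = PermutationEngine(sample, n_perm=n_perm, seed=seed, exact=exact)
    if int(engine.event_mask.sum()) < 2:
        raise ValueError("need at least two distinct event times")
    stats_all = _konp_statistics(engine, engine.n1, engine.n2, variant)
    p = engine.pvalue(stats_all)
    return TestResult(f"KONP_{variant}", float(stats_all[0]), p,
                      {"n_resamples": engine.R, "seed": seed})


def abc_test(sample: SurvivalSample, n_perm: int = 5000,
             seed: int | None = None, exact: bool = False) -> TestResult:
    """Area between the two KM curves, integrated up to the smaller arm-wise
    largest observed time, with a permutation p-value."""
    for j in (1, 2):
        if sample.arm(j)[1].sum() < 1:
            raise ValueError("both arms need at least one event")
    engine = PermutationEngine(sample, n_perm=n_perm, seed=seed, exact=exact)
    S1, S2 = engine.group_km()
    m1, m2 = engine.arm_max_times()
    tau_end = np.minimum(m1, m2)  # per replicate
    widths = engine.interval_widths(tau_end)
    D = np.sum(widths * np.abs(S1 - S2), axis=1)
    p = engine.pvalue(D)
    return TestResult("ABC", float(D[0]), p,
                      {"tau_end": float(tau_end[0]), "n_resamples": engine.R,
                       "seed": seed})


def two_stage_test(sample: SurvivalSample, alpha: float = 0.05,
                   split_eps: float = 0.5, n_boot: int = 5000,
                   seed: int | None = None, exact: bool = False) -> TestResult:
    """Two-stage procedure: log-rank first, then a crossing-weight test.

    Stage 1 runs the log-rank test at level ``split_eps * alpha``. If it
    fails to reject, stage 2 maximizes the absolute weighted log-rank score
    over sign-change weights w(t) = +1 for t <= c, -1 for t > c with the
    change point c ranging over the pooled event times, and calibrates the
    maximum by group-label permutation at level ``(1 - split_eps) * alpha``.
    The reported overall p-value min(1, min(p1/eps, p2/(1-eps))) makes
    "p <= alpha" equivalent to the staged decision.
    """
    if not 0.0 < split_eps < 1.0:
        raise ValueError("split_eps must be in (0, 1)")
    lr = logrank_test(sample)
    p1 = lr.p_value
    if p1 <= split_eps * alpha:
        return TestResult("2ST", lr.statistic, min(1.0, p1 / split_eps),
                          {"stage": 1, "p_stage1": p1, "p_stage2": float("nan"),
                           "seed": seed})

    engine = PermutationEngine(sample, n_perm=n_boot, seed=seed, exact=exact)
    U, Q = engine.wlr_increments()
    V = Q.sum(axis=1)
    k = U.shape[1]
    degenerate = k < 2 or V[0] <= 0
    if degenerate:
        return TestResult("2ST", lr.statistic, min(1.0, p1 / split_eps),
                          {"stage": 1, "p_stage1": p1, "p_stage2": float("nan"),
                           "degenerate": True, "seed": seed})
    cums = np.cumsum(U, axis=1)
    Z = 2.0 * cums[:, :-1] - cums[:, -1:]  # drop c = last event time (no sign change)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.abs(Z) / np.sqrt(np.maximum(V, 1e-300))[:, None]
    T[V <= 0] = 0.0
    stat = T.max(axis=1)
    p2 = engine.pvalue(stat)
    overall = min(1.0, min(p1 / split_eps, p2 / (1.0 - split_eps)))
    return TestResult("2ST", float(stat[0]), overall,
                      {"stage": 2, "p_stage1": p1, "p_stage2": p2,
                       "n_resamples": engine.R, "seed": seed})
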