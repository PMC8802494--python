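"""The weighted log-rank family.

A weighted log-rank statistic accumulates weighted observed-minus-expected
arm-1 event counts over the pooled risk sets:

    Z = sum_i w(t_i) (d_i1 - n_i1 d_i / n_i)
    V = sum_i w(t_i)^2 n_i1 n_i2 d_i (n_i - d_i) / (n_i^2 (n_i - 1))

with T = Z / sqrt(V) asymptotically standard normal under the null of equal
survival. The constant weight gives the classic log-rank test; the pooled
left-limit Kaplan–Meier value S(t-) gives the Peto–Peto test; the
Fleming–Harrington G(rho, gamma) family uses S(t-)^rho (1 - S(t-))^gamma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .core import EventTable, StepCurve, SurvivalSample, build_event_table, pooled_km_left
from .results import TestResult

__all__ = [
    "WeightSpec",
    "WlrResult",
    "wlr_statistic",
    "wlr_cov",
    "logrank_test",
    "peto_peto_test",
]


@dataclass(frozen=True)
class WeightSpec:
    """Weight function for a weighted log-rank statistic.

    kind:
        "constant"            w = 1 (log-rank),
        "peto"                w = S(t-), pooled KM left limit,
        "peto_modified"       w = S(t-) * n_i / (n_i + 1),
        "fleming_harrington"  w = S(t-)^rho (1 - S(t-))^gamma,
        "custom"              ``func`` applied to the pooled S(t-) values.
    """

    kind: str = "constant"
    rho: float = 0.0
    gamma: float = 0.0
    func: Callable[[np.ndarray], np.ndarray] | None = None
    label: str | None = None

    def __post_init__(self):
        if self.kind not in ("constant", "peto", "peto_modified",
                             "fleming_harrington", "custom"):
            raise ValueError(f"unknown weight kind {self.kind!r}")
        if self.rho < 0 or self.gamma < 0:
            raise ValueError("rho and gamma must be >= 0")
        if self.kind == "custom" and self.func is None:
            raise ValueError("custom weight requires func")

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.kind == "fleming_harrington":
            return f"FH({self.rho:g},{self.gamma:g})"
        return self.kind

    def evaluate(self, s_left: np.ndarray, n_risk: np.ndarray | None = None) -> np.ndarray:
        """Weights at the pooled event times given pooled S(t-) there."""
        s_left = np.asarray(s_left, dtype=float)
        if self.kind == "constant":
            return np.ones_like(s_left)
        if self.kind == "peto":
            return s_left.copy()
        if self.kind == "peto_modified":
            if n_risk is None:
                raise ValueError("peto_modified needs at-risk counts")
            return s_left * n_risk / (n_risk + 1.0)
        if self.kind == "fleming_harrington":
            return s_left**self.rho * (1.0 - s_left) ** self.gamma
        return np.asarray(self.func(s_left), dtype=float)


#: Fleming–Harrington grid used by the MaxCombo test by default.
FH_GRID = (
    WeightSpec("fleming_harrington", 0, 0),
    WeightSpec("fleming_harrington", 0, 1),
    WeightSpec("fleming_harrington", 1, 0),
    WeightSpec("fleming_harrington", 1, 1),
)

#: Crossing-direction weight: changes sign near the pooled median survival.
CROSSING_WEIGHT = WeightSpec("custom", func=lambda s: 1.0 - 2.0 * s, label="crossing")


@dataclass(frozen=True)
class WlrResult:
    score: float          # Z
    variance: float       # V >= 0
    standardized: float   # T = Z / sqrt(V); NaN when V = 0
    p_value: float
    weight: WeightSpec | None = None


def _hypergeom_terms(table: EventTable) -> np.ndarray:
    """Per-time conditional variance d_i n_i1 n_i2 (n_i - d_i) / (n_i^2 (n_i-1))."""
    n, n1, d = table.n_risk.astype(float), table.n_risk1.astype(float), table.d.astype(float)
    n2 = n - n1
    with np.errstate(divide="ignore", invalid="ignore"):
        v = n1 * n2 * d * (n - d) / (n**2 * (n - 1.0))
    v[table.n_risk <= 1] = 0.0
    return v


def _weights_at_events(table: EventTable, weight: WeightSpec, pooled_left: StepCurve) -> np.ndarray:
    s_left = np.asarray(pooled_left.left_limit(table.time), dtype=float)
    return weight.evaluate(s_left, n_risk=table.n_risk)


def wlr_statistic(table: EventTable, weight: WeightSpec,
                  pooled_left: StepCurve) -> WlrResult:
    """Weighted log-rank score, variance and two-sided chi-square(1) p-value."""
    if table.k < 1:
        raise ValueError("event table has no event times")
    w = _weights_at_events(table, weight, pooled_left)
    if not np.all(np.isfinite(w)):
        raise ValueError("non-finite weights")
    u = table.d1 - table.n_risk1 * table.d / table.n_risk
    z = float(np.sum(w * u))
    v = float(np.sum(w**2 * _hypergeom_terms(table)))
    if v <= 0.0:
        if abs(z) > 1e-10:
            raise RuntimeError("zero variance with nonzero score")
        return WlrResult(score=z, variance=0.0, standardized=float("nan"),
                         p_value=1.0, weight=weight)
    t = z / np.sqrt(v)
    p = float(stats.chi2.sf(t * t, df=1))
    return WlrResult(score=z, variance=v, standardized=float(t), p_value=p, weight=weight)


def wlr_cov(table: EventTable, weights: list[WeightSpec],
            pooled_left: StepCurve) -> np.ndarray:
    """Covariance matrix of the weighted log-rank scores for a list of weights.

    Cov(Z_a, Z_b) = sum_i w_a(t_i) w_b(t_i) * hypergeometric variance term.
    Symmetric PSD; the diagonal is each weight's variance V.
    """
    if len(weights) < 1:
        raise ValueError("need at least one weight")
    W = np.stack([_weights_at_events(table, w, pooled_left) for w in weights])
    v = _hypergeom_terms(table)
    return (W * v) @ W.T


def _wlr_test(sample: SurvivalSample, weight: WeightSpec, method: str,
              two_sided: bool = True) -> TestResult:
    table = build_event_table(sample)
    res = wlr_statistic(table, weight, pooled_km_left(sample))
    if two_sided:
        stat, p = res.standardized**2, res.p_value
    else:
        stat, p = res.standardized, float(stats.norm.sf(res.standardized))
    if res.variance == 0.0:
        stat, p = 0.0, 1.0
    return TestResult(method=method, statistic=stat, p_value=p,
                      metadata={"score": res.score, "variance": res.variance,
                                "weight": weight.name})


def logrank_test(sample: SurvivalSample, two_sided: bool = True) -> TestResult:
    """Classic (unweighted) log-rank test; chi-square(1) statistic."""
    return _wlr_test(sample, WeightSpec("constant"), "LR", two_sided)


def peto_peto_test(sample: SurvivalSample, modified: bool = False,
                   two_sided: bool = True) -> TestResult:
    """Peto–Peto test, weighting by the pooled KM left limit S(t-).

    ``modified=True`` uses the n/(n+1)-modified weight variant.
    """
    spec = WeightSpec("peto_modified" if modified else "peto")
    return _wlr_test(sample, spec, "PP", two_sided)
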