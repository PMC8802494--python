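"""Combination tests built on vectors of weighted log-rank scores.

Two ways to pool evidence from several weighted log-rank directions:

* the multiple-direction log-rank test (``mdir_test``) forms the Wald-type
  quadratic form S = Z' Sigma^+ Z from the score vector Z and its estimated
  covariance, i.e. a projection onto the alternative space spanned by the
  chosen weights, and calibrates it by group-label permutation;
* the MaxCombo test (``maxcombo_test``) takes the maximum of the
  standardized scores, M = max_a |T_a|, with a multivariate-normal or a
  permutation p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._perm import PermutationEngine
from .core import SurvivalSample
from .wlr import CROSSING_WEIGHT, FH_GRID, WeightSpec

__all__ = ["CombinationResult", "mdir_test", "maxcombo_test",
           "MDIR_DEFAULT_WEIGHTS", "MAXCOMBO_DEFAULT_WEIGHTS"]

#: mdir default directions: proportional hazards + a crossing direction
#: w(t) = 1 - 2 S(t-) that changes sign near the pooled median survival.
MDIR_DEFAULT_WEIGHTS = (WeightSpec("constant"), CROSSING_WEIGHT)

#: MaxCombo default: the four-element Fleming–Harrington grid
#: {(0,0), (0,1), (1,0), (1,1)} covering PH, late, early and middle effects.
MAXCOMBO_DEFAULT_WEIGHTS = FH_GRID


@dataclass(frozen=True)
class CombinationResult:
    method: str
    statistic: float
    p_value: float
    component_stats: np.ndarray = field(default=None)
    n_resamples: int = 0
    seed: int | None = None
    metadata: dict = field(default_factory=dict)


def _weight_matrix(engine: PermutationEngine, weights) -> np.ndarray:
    """Evaluate each weight at the pooled event times (perm-invariant)."""
    s_left = engine.pooled_left[engine.event_mask]
    n_risk = engine.n_pool[engine.event_mask]
    return np.stack([w.evaluate(s_left, n_risk=n_risk) for w in weights])


def _standardized(Z: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    V = np.diagonal(Sigma, axis1=-2, axis2=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(V > 0, Z / np.sqrt(np.maximum(V, 1e-300)), 0.0)
    return T


def mdir_test(sample: SurvivalSample,
              weights=MDIR_DEFAULT_WEIGHTS,
              n_perm: int = 5000,
              seed: int | None = None,
              exact: bool = False) -> CombinationResult:
    """Multiple-direction log-rank test with permutation inference.

    The statistic is S = Z' Sigma^+ Z where Z stacks the weighted log-rank
    scores and Sigma is their estimated covariance (pseudo-inverted, singular
    values below 1e-10 of the largest treated as zero). The p-value is the
    label-permutation tail proportion with the (1+k)/(1+B) correction, or the
    exact enumeration tail when ``exact=True``.
    """
    weights = list(weights)
    if len(weights) < 1:
        raise ValueError("mdir needs at least one weight")
    engine = PermutationEngine(sample, n_perm=n_perm, seed=seed, exact=exact)
    W = _weight_matrix(engine, weights)
    Z, Sigma = engine.wlr_scores(W)

    if not np.any(Sigma[0]):
        warnings.warn("all-zero covariance; mdir statistic undefined, p = 1")
        return CombinationResult("mdir", 0.0, 1.0,
                                 component_stats=np.zeros(len(weights)),
                                 n_resamples=engine.R, seed=seed)

    Sig_pinv = np.linalg.pinv(Sigma, rcond=1e-10, hermitian=True)
    S = np.einsum("ra,rab,rb->r", Z, Sig_pinv, Z)
    p = engine.pvalue(S)
    return CombinationResult(
        "mdir", float(S[0]), p,
        component_stats=_standardized(Z[0][None], Sigma[0][None])[0],
        n_resamples=engine.R, seed=seed,
        metadata={"weights": [w.name for w in weights]},
    )


def _unique_components(corr: np.ndarray) -> np.ndarray:
    """Indices of one representative per cluster of perfectly correlated
    components (reduces a singular correlation from duplicated weights)."""
    keep = []
    for a in range(corr.shape[0]):
        if not any(abs(corr[a, b]) > 1.0 - 1e-10 for b in keep):
            keep.append(a)
    return np.asarray(keep, dtype=int)


def maxcombo_test(sample: SurvivalSample,
                  weights=MAXCOMBO_DEFAULT_WEIGHTS,
                  method: str = "mvn",
                  n_resamples: int = 5000,
                  seed: int | None = None,
                  exact: bool = False) -> CombinationResult:
    """MaxCombo test: maximum of standardized weighted log-rank statistics.

    ``method="mvn"`` computes P(max_a |G_a| > M) for G multivariate normal
    with the estimated correlation of the scores (seeded quasi-Monte-Carlo
    integration). ``method="permutation"`` uses the group-label permutation
    distribution instead — preferable below roughly 30 subjects per arm.
    """
    weights = list(weights)
    if method not in ("mvn", "permutation"):
        raise ValueError("method must be 'mvn' or 'permutation'")
    n_perm = n_resamples if method == "permutation" else 0
    engine = PermutationEngine(sample, n_perm=max(n_perm, 0), seed=seed, exact=exact)
    W = _weight_matrix(engine, weights)
    Z, Sigma = engine.wlr_scores(W)
    T = _standardized(Z, Sigma)
    M = np.abs(T).max(axis=1)
    obs = float(M[0])
    comp = T[0]

    if method == "permutation":
        p = engine.pvalue(M)
        return CombinationResult("MaxCombo", obs, p, component_stats=comp,
                                 n_resamples=engine.R, seed=seed,
                                 metadata={"method": "permutation"})

    V = np.diag(Sigma[0])
    ok = V > 0
    if not np.any(ok):
        return CombinationResult("MaxCombo", 0.0, 1.0, component_stats=comp,
                                 n_resamples=0, seed=seed,
                                 metadata={"method": "mvn"})
    sd = np.sqrt(V[ok])
    corr = Sigma[0][np.ix_(ok, ok)] / np.outer(sd, sd)
    keep = _unique_components(corr)
    corr = corr[np.ix_(keep, keep)]
    m = corr.shape[0]
    if m == 1:
        p = 2.0 * float(stats.norm.sf(obs))
    else:
        inside = float(stats.multivariate_normal.cdf(
            np.full(m, obs), mean=np.zeros(m), cov=corr, allow_singular=True,
            maxpts=100_000, lower_limit=np.full(m, -obs),
            rng=np.random.default_rng(seed)))
        p = min(max(1.0 - inside, 0.0), 1.0)
    return CombinationResult("MaxCombo", obs, p, component_stats=comp,
                             n_resamples=0, seed=seed, metadata={"method": "mvn"})
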