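"""One-parameter two-sample Cox partial-likelihood fit (Breslow ties).

The model has a single binary covariate x = 1{arm 2}; beta is the log hazard
ratio of arm 2 versus arm 1. With d_i pooled events and n_i1, n_i2 at risk
at the distinct event times, the Breslow partial-likelihood score and
information are

    U(beta) = sum_i [ d_i2 - d_i * n_i2 e^b / (n_i1 + n_i2 e^b) ]
    I(beta) = sum_i   d_i * n_i1 n_i2 e^b / (n_i1 + n_i2 e^b)^2

solved by Newton iteration from beta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SurvivalSample, build_event_table


@dataclass(frozen=True)
class CoxFit:
    beta: float
    se: float
    converged: bool
    n_iter: int


def fit_two_sample_cox(sample: SurvivalSample, tol: float = 1e-8,
                       max_iter: int = 50) -> CoxFit:
    table = build_event_table(sample)
    d = table.d.astype(float)
    d2 = table.d2.astype(float)
    n1 = table.n_risk1.astype(float)
    n2 = table.n_risk2.astype(float)

    # monotone likelihood: every event time has one arm absent from the risk set
    informative = (n1 > 0) & (n2 > 0)
    if not np.any(informative):
        return CoxFit(beta=np.nan, se=np.nan, converged=False, n_iter=0)

    beta = 0.0
    for it in range(1, max_iter + 1):
        eb = np.exp(beta)
        denom = n1 + n2 * eb
        mu = n2 * eb / denom
        score = float(np.sum(d2 - d * mu))
        info = float(np.sum(d * mu * (n1 / denom)))
        if info <= 0:
            return CoxFit(beta=np.nan, se=np.nan, converged=False, n_iter=it)
        step = score / info
        beta += step
        if abs(beta) > 50:  # diverging: monotone likelihood
            return CoxFit(beta=np.nan, se=np.nan, converged=False, n_iter=it)
        if abs(step) < tol:
            eb = np.exp(beta)
            denom = n1 + n2 * eb
            info = float(np.sum(d * (n2 * eb / denom) * (n1 / denom)))
            return CoxFit(beta=beta, se=1.0 / np.sqrt(info), converged=True, n_iter=it)
    return CoxFit(beta=beta, se=np.nan, converged=False, n_iter=max_iter)
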