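"""Foundational survival containers and estimators.

Everything downstream — the weighted log-rank family, the combination and
omnibus tests, RMST inference and the curve reconstruction — consumes the
three containers defined here:

``SurvivalSample``
    subject-level two-arm right-censored data (time, status, group),
``EventTable``
    the counting-process skeleton: pooled distinct event times with pooled
    and per-group at-risk and event counts,
``StepCurve``
    a right-continuous non-increasing step function (a Kaplan–Meier
    estimate) with exact step integration and a left-limit accessor.

Tie convention: at a shared time, events precede censorings, i.e. a subject
censored at t is still in the risk set of an event at t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SurvivalSample",
    "EventTable",
    "StepCurve",
    "build_event_table",
    "kaplan_meier",
    "pooled_km_left",
    "integrate_step",
    "tau_rule",
]


@dataclass(frozen=True)
class SurvivalSample:
    """Two-arm right-censored survival data.

    Parameters
    ----------
    time : array of float
        Observed times, strictly positive.
    status : array of int
        Event indicator: 1 = event, 0 = right-censored.
    group : array
        Group labels; exactly two distinct values must be present.
        ``group_labels`` orders them (sorted by default); "arm 1" is the
        first label throughout the package.
    """

    time: np.ndarray
    status: np.ndarray
    group: np.ndarray
    group_labels: tuple = field(default=None)

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status)
        group = np.asarray(self.group)
        if time.ndim != 1 or time.shape != status.shape or time.shape != group.shape:
            raise ValueError("time, status and group must be 1-d arrays of equal length")
        if time.size == 0:
            raise ValueError("empty sample")
        if not np.all(time > 0):
            raise ValueError("all times must be strictly positive")
        if not np.all(np.isin(status, (0, 1))):
            raise ValueError("status must be 0 (censored) or 1 (event)")
        labels = self.group_labels
        uniq = np.unique(group)
        if labels is None:
            labels = tuple(uniq.tolist())
        else:
            labels = tuple(labels)
        if len(labels) != 2 or not set(uniq.tolist()) == set(labels):
            raise ValueError("exactly two group labels required, both present")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", np.asarray(status, dtype=np.int8))
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "group_labels", labels)

    # -- convenience accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def membership(self) -> np.ndarray:
        """Boolean mask: True where the subject belongs to arm 1 (first label)."""
        return np.asarray(self.group == self.group_labels[0])

    def arm(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """(time, status) of arm ``j`` (1 or 2)."""
        m = self.membership if j == 1 else ~self.membership
        return self.time[m], self.status[m]

    def swap_groups(self) -> "SurvivalSample":
        return SurvivalSample(self.time, self.status, self.group,
                              group_labels=(self.group_labels[1], self.group_labels[0]))


@dataclass(frozen=True)
class EventTable:
    """Pooled distinct event times with at-risk and event counts.

    Rows are the strictly increasing pooled event times ``t_1 < ... < t_k``;
    ``n_risk*`` are counts at risk just before each time, ``d*`` are event
    counts at each time; the ``1`` suffix refers to arm 1.
    """

    time: np.ndarray       # (k,)
    n_risk: np.ndarray     # (k,) pooled at risk
    n_risk1: np.ndarray    # (k,) arm-1 at risk
    d: np.ndarray          # (k,) pooled events
    d1: np.ndarray         # (k,) arm-1 events

    @property
    def n_risk2(self) -> np.ndarray:
        return self.n_risk - self.n_risk1

    @property
    def d2(self) -> np.ndarray:
        return self.d - self.d1

    @property
    def k(self) -> int:
        return self.time.size


def build_event_table(sample: SurvivalSample) -> EventTable:
    """Tabulate pooled distinct event times with risk-set and event counts.

    Censored subjects leave the risk set immediately *after* their time, so a
    censoring tied with an event still counts at risk for that event.
    """
    if sample.status.sum() < 1:
        raise ValueError("no events in sample")
    order = np.argsort(sample.time, kind="stable")
    t = sample.time[order]
    e = sample.status[order].astype(np.int64)
    b = sample.membership[order].astype(np.int64)
    n = t.size

    uniq, first = np.unique(t, return_index=True)
    # at risk just before each distinct time = subjects with time >= it
    n_risk_all = n - first
    csum_b = np.concatenate([[0], np.cumsum(b)])
    n_risk1_all = int(b.sum()) - csum_b[first]
    d_all = np.add.reduceat(e, first)
    d1_all = np.add.reduceat(e * b, first)

    ev = d_all > 0
    return EventTable(
        time=uniq[ev],
        n_risk=n_risk_all[ev],
        n_risk1=n_risk1_all[ev],
        d=d_all[ev],
        d1=d1_all[ev],
    )


@dataclass(frozen=True)
class StepCurve:
    """Right-continuous non-increasing step function starting at 1.

    ``knots`` are the jump times (strictly increasing); ``values[i]`` is the
    function value on ``[knots[i], knots[i+1])``. Before the first knot the
    value is 1. ``variance`` optionally carries the Greenwood variance at the
    knots.
    """

    knots: np.ndarray
    values: np.ndarray
    variance: np.ndarray | None = None

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if np.any(values > 1.0 + 1e-12) or np.any(values < -1e-12):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(np.diff(values) > 1e-12):
            raise ValueError("survival values must be non-increasing")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    def __call__(self, t) -> np.ndarray | float:
        """Right-continuous evaluation S(t); S(t) = 1 for t before the first knot."""
        t = np.asarray(t, dtype=float)
        if self.knots.size == 0:
            vals = np.ones_like(t)
        else:
            idx = np.searchsorted(self.knots, t, side="right") - 1
            vals = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return vals if vals.ndim else float(vals)

    def left_limit(self, t) -> np.ndarray | float:
        """Left-continuous evaluation S(t-)."""
        t = np.asarray(t, dtype=float)
        if self.knots.size == 0:
            vals = np.ones_like(t)
        else:
            idx = np.searchsorted(self.knots, t, side="left") - 1
            vals = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], 1.0)
        return vals if vals.ndim else float(vals)


def kaplan_meier(times, statuses) -> StepCurve:
    """Product-limit estimator for a single arm.

    Returns the KM curve with knots at the distinct event times and the
    Greenwood variance S(t)^2 * sum d_i / (n_i (n_i - d_i)) attached
    (the summand is dropped where n_i = d_i, the curve hits zero there).
    """
    times = np.asarray(times, dtype=float)
    statuses = np.asarray(statuses)
    if times.size == 0:
        raise ValueError("empty arm")
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = statuses[order].astype(np.int64)
    uniq, first = np.unique(t, return_index=True)
    n_risk = t.size - first
    d = np.add.reduceat(e, first)
    ev = d > 0
    uniq, n_risk, d = uniq[ev], n_risk[ev], d[ev]
    if uniq.size == 0:
        # no events: S identically 1
        return StepCurve(knots=np.empty(0), values=np.empty(0), variance=np.empty(0))
    surv = np.cumprod(1.0 - d / n_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_risk > d, d / (n_risk * (n_risk - d)), 0.0)
    var = surv**2 * np.cumsum(terms)
    return StepCurve(knots=uniq, values=surv, variance=var)


def pooled_km_left(sample: SurvivalSample) -> StepCurve:
    """Pooled (arms merged) Kaplan–Meier estimate.

    Use ``.left_limit`` for the S(t-) values that feed the Peto–Peto and
    Fleming–Harrington weights.
    """
    return kaplan_meier(sample.time, sample.status)


def integrate_step(curve: StepCurve, a: float, b: float) -> float:
    """Exact rectangle-sum integral of the step curve over [a, b]."""
    if a > b:
        raise ValueError("integration bounds must satisfy a <= b")
    if a == b:
        return 0.0
    # breakpoints of the integrand restricted to [a, b]
    inner = curve.knots[(curve.knots > a) & (curve.knots < b)]
    edges = np.concatenate([[a], inner, [b]])
    widths = np.diff(edges)
    heights = curve(edges[:-1])
    return float(np.sum(widths * np.asarray(heights)))


def tau_rule(sample: SurvivalSample) -> float:
    """Default RMST truncation time.

    90% of the smaller of the two arms' largest observed times (events and
    censorings both count).
    """
    t1, _ = sample.arm(1)
    t2, _ = sample.arm(2)
    return 0.9 * min(t1.max(), t2.max())
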