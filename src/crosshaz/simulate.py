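"""Two-arm survival scenario generator and Monte-Carlo evaluation harness.

Hazard models: exponential, Weibull, and piecewise exponential — the last
being the workhorse for early/late/crossing-difference scenarios, since
cutting the hazard rate at chosen breakpoints produces survival curves that
cross a controlled number of times (``crossing_times`` solves S1 = S2
analytically for piecewise-linear cumulative hazards).

``rejection_study`` runs a battery of tests over simulated replicates and
tabulates empirical rejection rates (type-I error under the null, power
otherwise), with per-replicate random substreams so that adding a test
never perturbs another test's data stream.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SurvivalSample

__all__ = [
    "Exponential", "Weibull", "PiecewiseExponential",
    "Censoring", "ScenarioSpec", "simulate_sample", "crossing_times",
    "rejection_study", "preset", "PRESET_NAMES", "read_scenario",
]


# ---------------------------------------------------------------------------
# hazard models


@dataclass(frozen=True)
class Exponential:
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def cumhaz(self, t):
        return self.rate * np.asarray(t, dtype=float)

    def inv_cumhaz(self, h):
        return np.asarray(h, dtype=float) / self.rate

    def survival(self, t):
        return np.exp(-self.cumhaz(t))

    @property
    def piecewise(self):
        return np.array([0.0]), np.array([self.rate])


@dataclass(frozen=True)
class Weibull:
    shape: float
    scale: float

    def __post_init__(self):
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    def cumhaz(self, t):
        return (np.asarray(t, dtype=float) / self.scale) ** self.shape

    def inv_cumhaz(self, h):
        return self.scale * np.asarray(h, dtype=float) ** (1.0 / self.shape)

    def survival(self, t):
        return np.exp(-self.cumhaz(t))

    piecewise = None


@dataclass(frozen=True)
class PiecewiseExponential:
    """Hazard constant at rates[j] on [breakpoints[j], breakpoints[j+1])
    with breakpoints[0] = 0 implied."""

    breakpoints: tuple   # interior breakpoints, increasing, > 0
    rates: tuple         # len(breakpoints) + 1 rates

    def __post_init__(self):
        bp = np.asarray(self.breakpoints, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if np.any(r <= 0):
            raise ValueError("rates must be positive")
        if bp.size + 1 != r.size:
            raise ValueError("need len(breakpoints) + 1 rates")
        if bp.size and (np.any(bp <= 0) or np.any(np.diff(bp) <= 0)):
            raise ValueError("breakpoints must be positive and increasing")
        object.__setattr__(self, "breakpoints", tuple(bp.tolist()))
        object.__setattr__(self, "rates", tuple(r.tolist()))

    def _grid(self):
        edges = np.concatenate([[0.0], np.asarray(self.breakpoints)])
        rates = np.asarray(self.rates)
        H_at = np.concatenate([[0.0], np.cumsum(rates[:-1] * np.diff(
            np.append(edges, np.inf))[:-1])])
        return edges, rates, H_at

    def cumhaz(self, t):
        t = np.asarray(t, dtype=float)
        edges, rates, H_at = self._grid()
        idx = np.searchsorted(edges, t, side="right") - 1
        return H_at[idx] + rates[idx] * (t - edges[idx])

    def inv_cumhaz(self, h):
        h = np.asarray(h, dtype=float)
        edges, rates, H_at = self._grid()
        idx = np.searchsorted(H_at, h, side="right") - 1
        return edges[idx] + (h - H_at[idx]) / rates[idx]

    def survival(self, t):
        return np.exp(-self.cumhaz(t))

    @property
    def piecewise(self):
        return (np.concatenate([[0.0], np.asarray(self.breakpoints)]),
                np.asarray(self.rates))


# ---------------------------------------------------------------------------
# censoring and scenarios


@dataclass(frozen=True)
class Censoring:
    """kind: "none", "uniform" (on (0, upper)) or "administrative" (at time)."""

    kind: str = "none"
    upper: float = 0.0
    at: float = 0.0

    def __post_init__(self):
        if self.kind not in ("none", "uniform", "administrative"):
            raise ValueError(f"unknown censoring kind {self.kind!r}")
        if self.kind == "uniform" and self.upper <= 0:
            raise ValueError("uniform censoring needs upper > 0")
        if self.kind == "administrative" and self.at <= 0:
            raise ValueError("administrative censoring time must be > 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "none":
            return np.full(n, np.inf)
        if self.kind == "uniform":
            return rng.uniform(0.0, self.upper, size=n)
        return np.full(n, float(self.at))


@dataclass(frozen=True)
class ScenarioSpec:
    arm1: object
    arm2: object
    censoring: Censoring = field(default_factory=Censoring)
    n_per_arm: int = 150
    seed: int | None = None
    name: str = "custom"

    def __post_init__(self):
        if self.n_per_arm < 2:
            raise ValueError("need at least 2 subjects per arm")


def simulate_sample(spec: ScenarioSpec,
                    rng: np.random.Generator | None = None) -> SurvivalSample:
    """Draw one two-arm sample by inverse-transform sampling of the hazards."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_per_arm
    times, statuses, groups = [], [], []
    for label, model in ((1, spec.arm1), (2, spec.arm2)):
        u = rng.uniform(size=n)
        event_t = model.inv_cumhaz(-np.log(u))
        cens_t = spec.censoring.draw(rng, n)
        obs = np.minimum(event_t, cens_t)
        # guard against zero observed times (uniform censoring can draw ~0)
        obs = np.maximum(obs, 1e-12)
        status = (event_t <= cens_t).astype(int)
        times.append(obs)
        statuses.append(status)
        groups.append(np.full(n, label))
    return SurvivalSample(np.concatenate(times), np.concatenate(statuses),
                          np.concatenate(groups))


# ---------------------------------------------------------------------------
# analytic crossing times


def crossing_times(model1, model2, t_max: float | None = None) -> list[float]:
    """Times t > 0 where S1(t) = S2(t), i.e. where the cumulative hazards meet.

    Exact piecewise-linear solve when both models have piecewise-constant
    hazards; otherwise bracketing + Brent root refinement on H1 - H2.
    """
    if model1 == model2:
        return []
    if getattr(model1, "piecewise", None) is not None and \
       getattr(model2, "piecewise", None) is not None:
        return _crossings_piecewise(model1, model2)
    return _crossings_numeric(model1, model2, t_max)


def _crossings_piecewise(m1, m2) -> list[float]:
    e1, r1 = m1.piecewise
    e2, r2 = m2.piecewise
    edges = np.unique(np.concatenate([e1, e2]))
    horizon = max(m1.inv_cumhaz(12.0), m2.inv_cumhaz(12.0))  # S ~ 6e-6
    edges = np.append(edges[edges < horizon], horizon)
    roots = []
    for a, b in zip(edges[:-1], edges[1:]):
        fa = float(m1.cumhaz(a) - m2.cumhaz(a))
        slope = float((r1[np.searchsorted(e1, a, side="right") - 1]) -
                      (r2[np.searchsorted(e2, a, side="right") - 1]))
        if slope == 0.0:
            continue
        t = a - fa / slope
        if a < t < b or (t == a and a > 0 and fa == 0.0 and not roots):
            # sign change guaranteed by nonzero slope through zero
            if t > 0 and not any(abs(t - r) < 1e-12 for r in roots):
                # confirm an actual sign change in a neighbourhood
                eps = min(1e-9, (b - a) / 10)
                before = float(m1.cumhaz(max(t - eps, 0)) - m2.cumhaz(max(t - eps, 0)))
                after = float(m1.cumhaz(t + eps) - m2.cumhaz(t + eps))
                if before * after < 0:
                    roots.append(float(t))
    return sorted(roots)


def _crossings_numeric(m1, m2, t_max) -> list[float]:
    from scipy.optimize import brentq
    if t_max is None:
        t_max = float(max(m1.inv_cumhaz(12.0), m2.inv_cumhaz(12.0)))
    grid = np.linspace(1e-9, t_max, 4001)
    f = m1.cumhaz(grid) - m2.cumhaz(grid)
    roots = []
    sign = np.sign(f)
    for i in np.nonzero(sign[:-1] * sign[1:] < 0)[0]:
        r = brentq(lambda t: float(m1.cumhaz(t) - m2.cumhaz(t)),
                   grid[i], grid[i + 1])
        if r > 1e-8 and not any(abs(r - q) < 1e-8 for q in roots):
            roots.append(float(r))
    return sorted(roots)


# ---------------------------------------------------------------------------
# named presets


def preset(name: str, n_per_arm: int = 150, seed: int | None = None) -> ScenarioSpec:
    """Named study scenarios.

    null        exp(1) vs exp(1), uniform(0, 3) censoring (~30% censored)
    ph          exp(1) vs exp(1.7), uniform(0, 3)
    early       early difference that fades: pw-exp(2 then 1 after t=0.5)
    late        late-emerging difference: pw-exp(1 then 2.5 after t=0.75)
    crossing-1  survival curves cross once (analytically at t = 1.5)
    crossing-2  three-piece hazard, two crossings (t = 0.8 and t = 1.4)
    """
    base = Exponential(1.0)
    table = {
        "null": (base, Exponential(1.0), Censoring("uniform", upper=3.0)),
        "ph": (base, Exponential(1.7), Censoring("uniform", upper=3.0)),
        "early": (base, PiecewiseExponential((0.5,), (2.0, 1.0)),
                  Censoring("uniform", upper=3.0)),
        "late": (base, PiecewiseExponential((0.75,), (1.0, 2.5)),
                 Censoring("uniform", upper=3.0)),
        "crossing-1": (base, PiecewiseExponential((0.5,), (2.0, 0.5)),
                       Censoring("uniform", upper=4.0)),
        "crossing-2": (base, PiecewiseExponential((0.3, 1.2), (2.0, 0.4, 2.2)),
                       Censoring("uniform", upper=4.0)),
    }
    if name not in table:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(table)}")
    arm1, arm2, cens = table[name]
    return ScenarioSpec(arm1=arm1, arm2=arm2, censoring=cens,
                        n_per_arm=n_per_arm, seed=seed, name=name)


PRESET_NAMES = ("null", "ph", "early", "late", "crossing-1", "crossing-2")


# ---------------------------------------------------------------------------
# Monte-Carlo harness


def rejection_study(spec: ScenarioSpec, tests, n_reps: int,
                    alpha: float = 0.05, seed: int | None = None,
                    n_resamples: int = 500,
                    collect_pvalues: bool = False) -> pd.DataFrame:
    """Empirical rejection rates of a list of tests over simulated replicates.

    ``tests`` is a list of battery method names (see ``crosshaz.battery``).
    Replicate r draws its data from the substream ``default_rng([seed, r])``;
    each test inside a replicate gets its own derived seed. A test raising
    on a replicate is recorded as NA for that replicate, never dropped.

    Returns a table with one row per test: rejection rate among non-NA
    replicates, its binomial standard error, and the NA count. With
    ``collect_pvalues=True`` the raw p-value matrix is attached in ``.attrs``.
    """
    from .battery import derive_seed, run_single
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tests = list(tests)
    master = 0 if seed is None else int(seed)
    P = np.full((n_reps, len(tests)), np.nan)
    for r in range(n_reps):
        rng = np.random.default_rng([master, r])
        sample = simulate_sample(spec, rng=rng)
        for c, name in enumerate(tests):
            try:
                res = run_single(sample, name,
                                 seed=derive_seed(master * 100003 + r, name),
                                 n_resamples=n_resamples, alpha=alpha)
                P[r, c] = res.p_value
            except Exception:
                P[r, c] = np.nan
    rows = []
    for c, name in enumerate(tests):
        ok = ~np.isnan(P[:, c])
        n_ok = int(ok.sum())
        rate = float(np.mean(P[ok, c] <= alpha)) if n_ok else float("nan")
        se = float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else float("nan")
        rows.append({"test": name, "rejection_rate": rate, "se": se,
                     "n_reps": n_reps, "n_na": n_reps - n_ok})
    out = pd.DataFrame(rows).set_index("test")
    out.attrs["alpha"] = alpha
    out.attrs["scenario"] = spec.name
    if collect_pvalues:
        out.attrs["pvalues"] = P
    return out


# ---------------------------------------------------------------------------
# scenario config files (INI-style key/value)


def read_scenario(path) -> ScenarioSpec:
    """Read a scenario config.

    Schema (INI)::

        [scenario]
        preset = crossing-1      ; shortcut: ignores [arm*]/[censoring]
        n_per_arm = 150
        seed = 42

    or explicit arms::

        [arm1]
        model = exponential
        rate = 1.0
        [arm2]
        model = piecewise_exponential
        breakpoints = 0.5
        rates = 2.0, 0.5
        [censoring]
        kind = uniform
        upper = 4.0
    """
    cp = configparser.ConfigParser(inline_comment_prefixes=(";", "#"))
    with open(path) as fh:
        cp.read_file(fh)
    sc = cp["scenario"] if "scenario" in cp else {}
    n = int(sc.get("n_per_arm", 150))
    seed = int(sc["seed"]) if "seed" in sc else None
    if "preset" in sc:
        return preset(sc["preset"], n_per_arm=n, seed=seed)

    def parse_model(section):
        kind = section["model"]
        if kind == "exponential":
            return Exponential(float(section["rate"]))
        if kind == "weibull":
            return Weibull(float(section["shape"]), float(section["scale"]))
        if kind == "piecewise_exponential":
            bp = tuple(float(x) for x in section.get("breakpoints", "").split(",")
                       if x.strip())
            rates = tuple(float(x) for x in section["rates"].split(","))
            return PiecewiseExponential(bp, rates)
        raise ValueError(f"unknown model {kind!r}")

    arm1 = parse_model(cp["arm1"])
    arm2 = parse_model(cp["arm2"])
    cens = Censoring()
    if "censoring" in cp:
        cs = cp["censoring"]
        cens = Censoring(cs.get("kind", "none"),
                         upper=float(cs.get("upper", 0.0)),
                         at=float(cs.get("at", 0.0)))
    return ScenarioSpec(arm1=arm1, arm2=arm2, censoring=cens,
                        n_per_arm=n, seed=seed)
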