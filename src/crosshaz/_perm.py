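"""Vectorized group-label permutation engine.

Every resampling test in the package permutes group labels while holding the
pooled (time, status) pairs fixed. Under that scheme the pooled risk sets,
pooled event counts and pooled Kaplan–Meier curve are invariant, so a
permutation replicate is fully described by which subjects carry the arm-1
label. The engine materializes all replicates as one boolean membership
matrix (replicates x subjects, subjects sorted by time) and derives, with
cumulative-sum and segment-reduction primitives, the per-replicate arm-1
at-risk counts, event counts and per-arm Kaplan–Meier step values at the
pooled distinct times. Statistic kernels then reduce those matrices to one
statistic per replicate.

Row 0 of every matrix is the observed assignment; rows 1..R are random
permutations, or — in exact mode — all C(n, n1) distinct assignments.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .core import SurvivalSample, kaplan_meier

_EXACT_LIMIT = 500_000


class PermutationEngine:
    """Shared per-replicate quantities for label-permutation tests."""

    def __init__(self, sample: SurvivalSample, n_perm: int = 5000,
                 seed: int | None = None, exact: bool = False):
        order = np.argsort(sample.time, kind="stable")
        self.t = sample.time[order]
        self.e = sample.status[order].astype(np.int64)
        b_obs = sample.membership[order].astype(np.int8)
        self.n = self.t.size
        self.n1 = int(b_obs.sum())
        self.n2 = self.n - self.n1
        self.exact = exact

        # pooled distinct observed times and pooled counts (perm-invariant)
        self.uniq_t, self.first = np.unique(self.t, return_index=True)
        self.n_pool = self.n - self.first
        self.d_pool = np.add.reduceat(self.e, self.first)
        self.event_mask = self.d_pool > 0
        pooled_km = kaplan_meier(sample.time, sample.status)
        self.pooled_left = np.asarray(pooled_km.left_limit(self.uniq_t), dtype=float)
        self.pooled_right = np.asarray(pooled_km(self.uniq_t), dtype=float)

        if exact:
            n_assign = _n_choose_k(self.n, self.n1)
            if n_assign > _EXACT_LIMIT:
                raise ValueError(f"exact enumeration infeasible: C({self.n},{self.n1}) "
                                 f"= {n_assign} assignments")
            rows = np.zeros((n_assign, self.n), dtype=np.int8)
            for r, idx in enumerate(combinations(range(self.n), self.n1)):
                rows[r, list(idx)] = 1
            self.B = np.concatenate([b_obs[None, :], rows], axis=0)
        else:
            rng = np.random.default_rng(seed)
            perms = rng.permuted(np.tile(b_obs, (n_perm, 1)), axis=1)
            self.B = np.concatenate([b_obs[None, :], perms], axis=0)
        self.R = self.B.shape[0] - 1  # replicates beyond the observed row

        self._cache: dict[str, tuple] = {}

    # -- per-replicate count matrices (rows = replicates, cols = distinct times)

    def group1_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(N1, D1): arm-1 at-risk and event counts at the pooled distinct times."""
        if "counts" not in self._cache:
            csum = np.cumsum(self.B, axis=1, dtype=np.int64)
            before = np.zeros((self.B.shape[0], self.first.size), dtype=np.int64)
            nz = self.first > 0
            before[:, nz] = csum[:, self.first[nz] - 1]
            N1 = self.n1 - before
            D1 = np.add.reduceat(self.B * self.e, self.first, axis=1)
            self._cache["counts"] = (N1, D1)
        return self._cache["counts"]

    def group_km(self) -> tuple[np.ndarray, np.ndarray]:
        """(S1, S2): per-arm KM values at the pooled distinct times, per replicate.

        Right-continuous; after an arm's last observation the curve carries
        its last value.
        """
        if "km" not in self._cache:
            N1, D1 = self.group1_counts()
            N2 = self.n_pool - N1
            D2 = self.d_pool - D1
            S1 = self._km_from_counts(N1, D1)
            S2 = self._km_from_counts(N2, D2)
            self._cache["km"] = (S1, S2)
        return self._cache["km"]

    @staticmethod
    def _km_from_counts(N: np.ndarray, D: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.where(N > 0, 1.0 - D / np.maximum(N, 1), 1.0)
        return np.cumprod(factors, axis=1)

    def arm_max_times(self) -> tuple[np.ndarray, np.ndarray]:
        """Largest observed time in each (permuted) arm, per replicate."""
        if "maxt" not in self._cache:
            m1 = (self.B * self.t).max(axis=1)
            m2 = ((1 - self.B) * self.t).max(axis=1)
            self._cache["maxt"] = (m1, m2)
        return self._cache["maxt"]

    # -- weighted log-rank building blocks at the event times -----------------

    def wlr_increments(self) -> tuple[np.ndarray, np.ndarray]:
        """(U, Q) at pooled event times: score increments and variance terms.

        U[r, i] = d_i1 - n_i1 d_i / n_i for replicate r;
        Q[r, i] = n_i1 n_i2 d_i (n_i - d_i) / (n_i^2 (n_i - 1)), 0 when n_i <= 1.
        """
        if "wlr" not in self._cache:
            ev = self.event_mask
            N1, D1 = self.group1_counts()
            N1, D1 = N1[:, ev].astype(float), D1[:, ev].astype(float)
            n = self.n_pool[ev].astype(float)
            d = self.d_pool[ev].astype(float)
            U = D1 - N1 * d / n
            with np.errstate(divide="ignore", invalid="ignore"):
                c = np.where(n > 1, d * (n - d) / (n**2 * (n - 1.0)), 0.0)
            Q = N1 * (n - N1) * c
            self._cache["wlr"] = (U, Q)
        return self._cache["wlr"]

    def wlr_scores(self, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Scores and covariance matrices for a stack of weight vectors.

        ``W`` is (m, k_events): each row a weight evaluated at the pooled
        event times. Returns Z (replicates, m) and Sigma (replicates, m, m).
        """
        U, Q = self.wlr_increments()
        Z = U @ W.T
        Sigma = np.einsum("rk,ak,bk->rab", Q, W, W, optimize=True)
        return Z, Sigma

    # -- step-function integration helpers ------------------------------------

    def interval_widths(self, tau) -> np.ndarray:
        """Widths of the constancy intervals of the pooled-time step grid,
        truncated at ``tau`` (scalar or one value per replicate).

        Column i is the width of [T_i, T_{i+1}) ∩ [0, tau], with the last
        interval extending to tau. The implicit initial interval [0, T_1)
        (where every KM curve is 1) is NOT included.
        """
        tau = np.atleast_1d(np.asarray(tau, dtype=float))[:, None]
        t_lo = self.uniq_t[None, :]
        t_hi = np.concatenate([self.uniq_t[1:], [np.inf]])[None, :]
        return np.clip(np.minimum(t_hi, tau) - np.minimum(t_lo, tau), 0.0, None)

    def head_width(self, tau) -> np.ndarray:
        """Width of the initial interval [0, min(T_1, tau)] where S = 1."""
        tau = np.atleast_1d(np.asarray(tau, dtype=float))
        return np.minimum(self.uniq_t[0], tau)

    # -- p-values --------------------------------------------------------------

    def pvalue(self, stats: np.ndarray) -> float:
        """Permutation p-value for the per-replicate statistics (row 0 observed).

        Monte-Carlo mode applies the (1 + #{>= obs}) / (1 + R) finite-sample
        correction; exact mode returns the exact tail proportion over all
        assignments (which includes the observed one, so p > 0).
        """
        obs = stats[0]
        tol = 1e-12 * max(1.0, abs(obs))
        exceed = stats[1:] >= obs - tol
        if self.exact:
            return float(np.mean(exceed))
        return float((1 + exceed.sum()) / (1 + self.R))


def _n_choose_k(n: int, k: int) -> int:
    from math import comb
    return comb(n, k)
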