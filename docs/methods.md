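# Methods

`crosshaz` implements a battery of eleven two-sample tests for
right-censored survival data, aimed at the situation where the two arms'
hazard functions are not proportional — in particular where the survival
curves cross — plus the supporting machinery: Kaplan–Meier estimation,
reconstruction of pseudo individual-patient data (IPD) from published KM
figures, and a Monte-Carlo harness for size/power studies.

## Data model and conventions

A `SurvivalSample` holds subject-level `(time, status, group)` with
`status = 1` for an event and `0` for right censoring; exactly two group
labels are required and the first (sorted) label is "arm 1" everywhere.
Times are strictly positive in whatever unit the input uses; no unit
conversion is attempted. Ties between events and censorings at the same
time are resolved events-first: a subject censored at *t* is still in the
risk set of an event at *t* (the standard counting-process convention).

The `EventTable` tabulates, at the pooled distinct event times
t_1 < … < t_k, the pooled and arm-1 at-risk counts (n_i, n_i1) and event
counts (d_i, d_i1). Every test statistic in the package is a function of
this skeleton and/or the arm-wise KM curves.

## The weighted log-rank family

For a weight function w evaluated at the pooled event times,

    Z = Σ_i w(t_i) (d_i1 − n_i1 d_i / n_i)
    V = Σ_i w(t_i)² · n_i1 n_i2 d_i (n_i − d_i) / (n_i² (n_i − 1))

with T = Z/√V asymptotically standard normal under H0: S1 = S2. Terms at
times with n_i = 1 contribute 0 to V (the n_i − 1 denominator). Two-sided
inference uses χ²₁ on T²; a one-sided z-test is available by flag.

Weights: constant (log-rank, LR), the pooled-KM left limit Ŝ(t−)
(Peto–Peto, PP; the n/(n+1)-modified variant is an option but not the
default — the literature mostly names the test, not the variant), and the
Fleming–Harrington family G(ρ,γ): w = Ŝ(t−)^ρ (1 − Ŝ(t−))^γ. All
data-dependent weights use the *left limit* of the pooled KM so that the
weight at the first event time is well defined for γ > 0.

Cross-weight covariances Cov(Z_a, Z_b) replace w² by w_a w_b in V; the
resulting matrix is symmetric PSD with the per-weight variances on the
diagonal.

## Combination tests

**mdir** stacks several weighted log-rank scores into Z and forms the
Wald-type statistic S = Zᵀ Σ̂⁺ Z (Moore–Penrose pseudo-inverse; singular
values below 1e-10 of the largest are treated as zero). The default
directions are the constant weight (proportional-hazards direction) and
the crossing direction w(t) = 1 − 2Ŝ(t−), which changes sign near the
pooled median survival. Inference is by group-label permutation: labels
are reshuffled holding the pooled (time, status) pairs fixed, and
p = (1 + #{S_perm ≥ S_obs}) / (1 + B), so a permutation p-value is never
exactly zero.

**MaxCombo** takes M = max_a |T_a| over standardized weighted log-rank
statistics, by default over the Fleming–Harrington grid
{(0,0), (0,1), (1,0), (1,1)}. The default p-value is
1 − P(max_a |G_a| ≤ M) for G multivariate normal with the estimated score
correlation, computed by seeded quasi-Monte-Carlo integration
(`scipy.stats.multivariate_normal.cdf`, 1e5 integration points — absolute
error well below 1e-4 and bit-reproducible for a fixed seed). Perfectly
correlated components (duplicated weights) are reduced to one
representative before integration. A permutation variant is provided and
recommended below roughly 30 subjects per arm, where the normal
approximation is doubtful.

## RMST tests

The restricted mean survival time μ(τ) = ∫₀^τ Ŝ(t) dt is computed by exact
rectangle-sum integration of the KM step function; its variance is the
standard asymptotic sum Σ_{t_i ≤ τ} A_i² d_i / (n_i (n_i − d_i)) with
A_i = ∫_{t_i}^τ Ŝ. Default τ is the 90%-of-minimum-maximum rule: 0.9 times
the smaller of the two arms' largest observed times (events or
censorings); it is user-overridable, and `rmst` refuses a τ beyond an
arm's follow-up.

* **RMST2**: z = (μ̂₁ − μ̂₂)/√(V₁+V₂), two-sided normal p.
* **RMST1**: the same difference calibrated by group-label permutation.
  Permutation was chosen as the resampling scheme because it is exact
  under the strong null of equal distributions; a perturbation/bootstrap
  scheme would target the weaker equal-RMST null. Under relabelling an
  arm's KM curve is carried forward as a constant beyond its last
  observation so the statistic is defined for every relabelling at the
  fixed observed-data τ.
* **coxRMST**: Bonferroni combination p = min(1, 2·min(p_cox, p_rmst)) of
  a two-sample Cox Wald test and RMST1. The exact combination rule used
  by the original (closed-source) implementation is not documented;
  Bonferroni is a deliberately conservative stand-in. If the Cox fit is
  non-identified (monotone likelihood) the test falls back to the RMST
  p-value with a warning.

The Cox fit itself is the one-parameter two-group partial likelihood with
Breslow tie handling, solved by Newton iteration from β = 0 (convergence
|Δβ| < 1e-8, max 50 iterations, divergence beyond |β| > 50 reported as
monotone likelihood).

## Omnibus tests

**KONP-style partition tests.** At every pooled event time t the sample is
cross-classified into arm × {failed by t, survived past t}. Censored-
before-t subjects are allocated fractionally through the arm-wise KM:
the "failed" cell of arm j is n_j (1 − Ŝ_j(t)). The statistic sums the
Pearson χ² ("chi") or likelihood-ratio 2·Σ O log(O/E) ("llr")
contributions over event times, with expectations from the table margins,
0·log 0 = 0, and degenerate tables (an empty margin) contributing 0.
Calibration is by group-label permutation with arm-wise KM curves
recomputed for every relabelling. This fractional-allocation variant is
the implemented definition; the originally published partition tests
differ in the fine structure of their censoring imputation, and the
simulation suite verifies that this variant holds its size and has the
expected omnibus power profile.

**ABC.** The integrated L1 distance D = ∫₀^{τ_end} |Ŝ₁ − Ŝ₂| dt with
τ_end the smaller of the two arms' largest observed times — integrating
further would extrapolate a KM curve beyond its follow-up. Exact
step-function integration; permutation p-value (τ_end is recomputed for
each relabelling).

**Two-stage (2ST).** Stage 1 is the log-rank test at level ε·α (ε = 0.5
by default, configurable). If it fails to reject, stage 2 uses the
sign-change weight w(t) = +1 for t ≤ c, −1 for t > c, maximizing the
absolute standardized score over change points c at the pooled event
times (the last event time is excluded — no sign change there; with ±1
weights the variance does not depend on c). The stage-2 maximum is
calibrated by permutation at level (1−ε)α. The reported overall p-value
min(1, min(p₁/ε, p₂/(1−ε))) makes "p ≤ α" coincide with the staged
decision and keeps the overall size at or below α; because the two
stages probe nearly orthogonal directions, the procedure is only mildly
conservative in practice (measured size ≈ 0.04–0.06 at n = 150/arm).

### Permutation engine

All permutation tests share one vectorized engine: the B relabellings are
materialized as a (B+1) × n boolean membership matrix (row 0 = observed),
from which arm-wise at-risk counts, event counts and KM step values at the
pooled distinct times are derived by cumulative sums and segment
reductions. This keeps a full 11-test battery at B = 500 under ~0.3 s for
n = 300 subjects. For tiny samples every test accepts `exact=True`, which
enumerates all C(n, n1) label assignments and returns the exact
permutation p (capped at 5·10⁵ assignments).

Statistic ties in the tail count are resolved with a relative tolerance of
1e-12 so that exact ties count as "as extreme".

## Reconstruction of pseudo-IPD

Inputs per arm: digitized KM step coordinates (time, survival), the
number-at-risk table (time, count), and optionally the total event count.
Within each inter-risk-table interval the solver places a trial number of
censorings uniformly over the interval (the usual non-informative
censoring assumption), interleaves them with the digitized steps, derives
integer event counts at each step by rounding n_k (1 − S_k / KM̂) against
the running reconstructed KM (which self-corrects rounding drift), and
keeps the censoring count whose resulting at-risk count at the next
risk-table time matches the printed count *exactly* — among all exactly
matching counts, the one whose reconstructed KM best fits the digitized
values. This exhaustive scan replaces the classic fixed-point iteration
on the censoring count, which can converge to allocations that satisfy
the risk constraint but visibly misfit the curve when only one or two
subjects are at risk. An exact risk-count match is a hard invariant;
an interval with no matching allocation raises an error naming the
interval. After the last risk-table time, censorings default to zero
unless a total event count is given, in which case residual censorings
are chosen to match it (gap first, curve fit as tie-break). Digitized
survival values are trusted over implied event counts at the rounding
level; subjects still at risk after the last digitized step are censored
there.

Quality assessment follows the usual protocol: per-arm median survival
(smallest t with Ŝ(t) ≤ 0.5, reported as undefined when the curve never
reaches 0.5) and the Cox HR with Wald 95% CI, side by side with the
published values.

**What the round trip does and does not show.** `exact_digitization`
emulates an error-free plot digitizer (exact step coordinates, risk table
on a regular grid, curve extended to the end of follow-up). Under
administrative censoring (a fixed data cutoff) the reconstruction is then
exact: every statistic and p-value of the battery is reproduced to the
bit. Under continuous (e.g. uniform) censoring the *within-interval
censoring times* are information the published format simply does not
carry; reconstruction then reproduces the KM to ~0.01–0.03 sup-distance
and the HR to a few percent, and mid-range p-values can move by several
hundredths. The acceptance round-trip study therefore uses administrative-
censoring scenarios (where the tolerance is meaningful), and a separate
robustness test documents the uniform-censoring behaviour at looser
tolerances. Real digitizations add pixel noise on top of both regimes.

## Simulation harness

Event times are drawn by inverse-transform sampling of the cumulative
hazard (exponential, Weibull, piecewise exponential); censoring is none,
uniform(0, c) or administrative (fixed time). `crossing_times` solves
S₁ = S₂ analytically for piecewise-constant hazards (piecewise-linear
cumulative hazards; tangential touches are not counted) and by bracketed
root-finding otherwise.

Named presets fix the study conditions used throughout the tests and the
acceptance script, all with arm 1 ~ exponential(1):

| preset | arm 2 hazard | censoring | remark |
|---|---|---|---|
| `null` | 1 | U(0,3) | ≈ 32% censored |
| `ph` | 1.7 | U(0,3) | proportional hazards |
| `early` | 2 on [0,0.5), then 1 | U(0,3) | early difference |
| `late` | 1 on [0,0.75), then 2.5 | U(0,3) | late difference |
| `crossing-1` | 2 on [0,0.5), then 0.5 | U(0,4) | curves cross at t = 1.5 |
| `crossing-2` | 2 / 0.4 / 2.2 (breaks 0.3, 1.2) | U(0,4) | crossings at t = 0.8, 1.4 |

The uniform(0,3) dropout gives a realistic ~30% censoring fraction for an
exponential(1) arm. Replicate r of a study draws its data from the
substream `default_rng([seed, r])` and each test inside a replicate gets
its own seed derived from the master seed and the method name (CRC32), so
adding or removing a test never perturbs another test's data or p-value.
A test that errors on a replicate is recorded as NA, never dropped.

## Problem sizes

The shipped test-suite and acceptance-script scales are: size study 1000
replicates at n = 150/arm with 500 inner resamples; power/concordance
studies 500 replicates; reconstruction round trip 50 scenarios at
n = 200/arm with 1000 inner resamples; full-precision analyses use 5000
resamples (the battery default). At these scales the whole suite runs in
a few minutes on one CPU; rates carry binomial standard errors of about
0.007–0.010, which is the resolution at which the size/power statements
should be read.

## Known limitations

* Two arms only; no stratification, left truncation, interval censoring
  or competing risks.
* The coxRMST Bonferroni combination is conservative by construction:
  the Cox and RMST p-values are strongly positively correlated under the
  null, so its empirical size sits near 0.03 rather than the nominal
  0.05 (visible in the size study the acceptance script reports).
* The KONP variant implemented here is the fractional-allocation
  definition described above, not a line-by-line port of the original.
* MaxCombo's default mvn p-value leans on asymptotic normality of the
  score vector; use `method="permutation"` for small samples.
* Reconstruction assumes non-informative censoring spread uniformly
  within risk-table intervals; informative or highly clustered dropout
  will bias the rebuilt IPD in ways the quality report may not reveal.
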