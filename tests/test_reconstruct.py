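import dataclasses

import numpy as np
import pytest

from crosshaz import (ArmDigitization, DigitizedInput, SurvivalSample, cox_hr,
                      kaplan_meier, median_survival, preset, quality_report,
                      reconstruct_ipd, simulate_sample)
from crosshaz.core import StepCurve
from crosshaz.reconstruct import ReconstructionError, exact_digitization


def _admin_scenario(rep, n_per_arm=200):
    names = ["crossing-1", "ph", "null", "late", "early"]
    base = preset(names[rep % 5], n_per_arm=n_per_arm)
    admin = 1.5 + (rep % 7) * 0.25
    from crosshaz import Censoring
    spec = dataclasses.replace(base, censoring=Censoring("administrative", at=admin))
    return simulate_sample(spec, rng=np.random.default_rng([1000, rep]))


def _risk_counts(sample_times, grid):
    t = np.sort(sample_times)
    return t.size - np.searchsorted(t, grid, side="left")


class TestReconstructIpd:
    def test_round_trip_reproduces_km_and_risk_counts(self):
        s = _admin_scenario(0)
        grid = np.arange(0.0, s.time.max() + 0.25, 0.5)
        inp = exact_digitization(s, grid)
        recon = reconstruct_ipd(inp)
        assert recon.max_km_deviation < 0.01
        # hard invariant: at-risk counts at the risk-table times match exactly
        for j, arm in ((1, inp.arm1), (2, inp.arm2)):
            t_rec, _ = recon.sample.arm(j)
            got = _risk_counts(t_rec, arm.risk_times)
            np.testing.assert_array_equal(got, arm.risk_counts)
            assert t_rec.size == arm.risk_counts[0]

    def test_no_censoring_closed_form(self):
        # without censoring, risk drops equal the survival-step implied deaths
        rng = np.random.default_rng(51)
        t = np.round(rng.exponential(1.0, 80) + 0.05, 2)
        s = SurvivalSample(np.concatenate([t, t + 0.005]),
                           np.ones(160), np.repeat([1, 2], 80))
        grid = np.arange(0.0, s.time.max() + 0.25, 0.5)
        recon = reconstruct_ipd(exact_digitization(s, grid))
        assert recon.sample.status.sum() == 160  # events only
        assert recon.max_km_deviation < 1e-9

    def test_constant_survival_all_censored_uniformly(self):
        arm = ArmDigitization([0.0, 4.0], [1.0, 1.0],
                              [0.0, 1.0, 2.0, 3.0, 4.0], [20, 15, 10, 5, 1])
        inp = DigitizedInput(arm, arm)
        recon = reconstruct_ipd(inp)
        assert recon.sample.status.sum() == 0
        t1, _ = recon.sample.arm(1)
        assert t1.size == 20
        # censor times spread over the follow-up, not piled at one point
        assert np.unique(t1).size > 10

    def test_infeasible_inputs_rejected(self):
        with pytest.raises(ReconstructionError):
            ArmDigitization([0.0, 1.0], [1.0, 1.1], [0.0, 1.0], [10, 5])
        with pytest.raises(ReconstructionError):
            ArmDigitization([0.0, 1.0], [1.0, 0.5], [0.0, 1.0], [10, 15])

    def test_uniform_censoring_round_trip_is_approximate(self):
        # uniform dropout: within-interval censoring times are information
        # the published format does not carry, so the round trip is close
        # but not exact
        s = simulate_sample(preset("ph", n_per_arm=200),
                            rng=np.random.default_rng(52))
        grid = np.arange(0.0, s.time.max() + 0.25, 0.5)
        inp = exact_digitization(s, grid)
        inp = DigitizedInput(dataclasses.replace(inp.arm1, total_events=None),
                             dataclasses.replace(inp.arm2, total_events=None))
        recon = reconstruct_ipd(inp)
        assert recon.max_km_deviation < 0.05
        hr0, hr1 = cox_hr(s)[0], cox_hr(recon.sample)[0]
        assert abs(hr1 - hr0) / hr0 < 0.05


class TestCoxHr:
    def test_null_hr_near_one(self):
        rng = np.random.default_rng(53)
        t = rng.exponential(1.0, 400)
        s = SurvivalSample(t, np.ones(400), np.tile([1, 2], 200))
        hr, lo, hi = cox_hr(s)
        assert lo < 1.0 < hi

    def test_exponential_rate_ratio_recovered(self):
        rng = np.random.default_rng(54)
        t = np.concatenate([rng.exponential(1.0, 500),
                            rng.exponential(0.5, 500)])
        s = SurvivalSample(t, np.ones(1000), np.repeat([1, 2], 500))
        hr, lo, hi = cox_hr(s)
        se = (np.log(hi) - np.log(hr)) / 1.96
        assert abs(np.log(hr) - np.log(2.0)) < 3 * se

    def test_label_swap_inverts_hr(self):
        rng = np.random.default_rng(55)
        t = np.concatenate([rng.exponential(1.0, 100),
                            rng.exponential(0.6, 100)])
        s = SurvivalSample(t, np.ones(200), np.repeat([1, 2], 100))
        hr, lo, hi = cox_hr(s)
        hr2, lo2, hi2 = cox_hr(s.swap_groups())
        assert hr2 == pytest.approx(1 / hr, rel=1e-9)
        assert lo2 == pytest.approx(1 / hi, rel=1e-9)

    def test_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter
        s = simulate_sample(preset("ph", n_per_arm=150),
                            rng=np.random.default_rng(56))
        hr, _, _ = cox_hr(s)
        df = pd.DataFrame({"t": s.time, "e": s.status,
                           "x": (s.group == 2).astype(int)})
        fit = CoxPHFitter().fit(df, "t", "e")
        assert np.log(hr) == pytest.approx(fit.params_.iloc[0], abs=1e-6)

    def test_monotone_likelihood_raises(self):
        # all events in one arm, none in the other arrangement that
        # separates the partial likelihood
        s = SurvivalSample([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], [1, 1, 2, 2])
        with pytest.raises(RuntimeError, match="non-identified"):
            cox_hr(s)


class TestMedianSurvival:
    def test_first_time_at_or_below_half(self):
        c = StepCurve([1.0, 3.0], [0.7, 0.4])
        assert median_survival(c) == 3.0

    def test_undefined_when_curve_stays_high(self):
        c = StepCurve([1.0, 2.0], [0.9, 0.6])
        assert median_survival(c) is None

    def test_plateau_at_exactly_half_takes_first_attainment(self):
        c = StepCurve([2.0, 5.0], [0.5, 0.2])
        assert median_survival(c) == 2.0

    def test_matches_lifelines_median(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(57)
        t = rng.exponential(1.0, 201)
        km = kaplan_meier(t, np.ones(201))
        kmf = KaplanMeierFitter().fit(t, np.ones(201))
        assert median_survival(km) == pytest.approx(kmf.median_survival_time_)


class TestQualityReport:
    def test_round_trip_deviations_small(self):
        s = _admin_scenario(1)
        grid = np.arange(0.0, s.time.max() + 0.25, 0.5)
        recon = reconstruct_ipd(exact_digitization(s, grid))
        km1, km2 = kaplan_meier(*s.arm(1)), kaplan_meier(*s.arm(2))
        reported = {"ms1": median_survival(km1), "ms2": median_survival(km2),
                    "hr": cox_hr(s)[0]}
        reported = {k: v for k, v in reported.items() if v is not None}
        rep = quality_report(recon, reported)
        rel = rep.set_index("quantity")["rel_dev"].dropna()
        assert (rel < 0.05).all()

    def test_missing_published_values_render_as_nan(self):
        s = _admin_scenario(2)
        grid = np.arange(0.0, s.time.max() + 0.25, 0.5)
        recon = reconstruct_ipd(exact_digitization(s, grid))
        rep = quality_report(recon, {})
        assert rep["published"].isna().all()
        assert rep["abs_dev"].isna().all()

    def test_identical_values_zero_deviation(self):
        s = _admin_scenario(3)
        grid = np.arange(0.0, s.time.max() + 0.25, 0.5)
        recon = reconstruct_ipd(exact_digitization(s, grid))
        hr, _, _ = cox_hr(recon.sample)
        rep = quality_report(recon, {"hr": hr}).set_index("quantity")
        assert rep.loc["hr", "abs_dev"] == pytest.approx(0.0)
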