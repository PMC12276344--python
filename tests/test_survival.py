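"""Endpoints, Kaplan-Meier, log-rank, Cox (fixed & time-varying), landmark."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import brentq

from ctdnamon.pipeline import classify_cohort
from ctdnamon.simulate import generate, scenario
from ctdnamon.survival import (ConvergenceError, SurvivalRecord,
                               attach_switch_times, build_endpoints, cox_fit,
                               failure_rate_at, km_fit, landmark_analysis,
                               logrank, split_time_varying)
from helpers import build_cohort, patient_row, sample_row
from oracles import km_oracle


def rec(pid, dur, event, switch=None, **cov):
    return SurvivalRecord(pid, dur, event, cov or None, switch)


class TestEndpoints:
    def test_ttf_arithmetic(self):
        cohort = build_cohort(
            [patient_row("P1", end_day=365, failure=True)],
            [sample_row("P1", -3, 1.0), sample_row("P1", 90, 0.2)], [])
        ttf, _ = build_endpoints(cohort)
        assert ttf[0].duration_months == pytest.approx(11.99, abs=0.01)
        assert ttf[0].event

    def test_alive_on_treatment_censored_both_endpoints(self):
        cohort = build_cohort(
            [patient_row("P1", followup_day=600)],
            [sample_row("P1", -3, 1.0), sample_row("P1", 90, 0.2)], [])
        ttf, os_ = build_endpoints(cohort)
        assert not ttf[0].event and not os_[0].event
        assert ttf[0].duration_months == os_[0].duration_months

    def test_cdk_only_discontinuation_is_not_a_failure(self):
        # both agents must stop: failure flag is the authority, and a
        # non-failing patient is censored at last follow-up even when a
        # treatment_end date exists
        cohort = build_cohort(
            [patient_row("P1", end_day=200, failure=False, followup_day=600)],
            [sample_row("P1", -3, 1.0), sample_row("P1", 90, 0.2)], [])
        ttf, _ = build_endpoints(cohort)
        assert not ttf[0].event
        assert ttf[0].duration_months == pytest.approx(600 / 30.4375)

    def test_negative_duration_names_patient(self):
        cohort = build_cohort(
            [patient_row("P7", followup_day=-30)],
            [sample_row("P7", -3, 1.0), sample_row("P7", 5, 0.5)], [])
        with pytest.raises(ValueError, match="P7"):
            build_endpoints(cohort)


class TestKaplanMeier:
    def test_no_events_survival_one_median_absent(self):
        km = km_fit([rec(f"P{i}", 10.0, False) for i in range(5)])
        assert np.all(km.survival == 1.0)
        assert km.median is None

    def test_three_event_closed_form(self):
        km = km_fit([rec("A", 1, True), rec("B", 2, True), rec("C", 3, True)])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2) == pytest.approx(1 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)
        assert km.median == pytest.approx(2.0)

    def test_uncensored_km_equals_empirical_survivor(self, rng):
        durations = rng.exponential(10, 60)
        records = [rec(f"P{i}", float(d), True)
                   for i, d in enumerate(durations)]
        km = km_fit(records)
        for t in [1.0, 5.0, 12.0, 25.0]:
            assert km.survival_at(t) == pytest.approx(
                np.mean(durations > t), abs=1e-12)

    def test_censored_mixture_matches_hand_oracle(self, rng):
        durations = rng.exponential(10, 80)
        events = rng.random(80) < 0.6
        records = [rec(f"P{i}", float(d), bool(e))
                   for i, (d, e) in enumerate(zip(durations, events))]
        km = km_fit(records)
        times, surv = km_oracle(durations, events)
        for t, s in zip(times, surv):
            assert km.survival_at(t) == pytest.approx(s, abs=1e-12)

    def test_exponential_simulation_converges_to_closed_form(self, rng):
        lam, n = 0.1, 2000
        durations = rng.exponential(1 / lam, n)
        censor = np.minimum(durations, 30.0)
        records = [rec(f"P{i}", float(c), bool(d <= 30.0))
                   for i, (d, c) in enumerate(zip(durations, censor))]
        km = km_fit(records)
        for t in [2.0, 5.0, 10.0, 20.0]:
            assert km.survival_at(t) == pytest.approx(np.exp(-lam * t),
                                                      abs=0.03)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        grp = [rec("A", 1, True), rec("B", 2, True), rec("C", 5, False)]
        dup = [rec(r.patient_id + "x", r.duration_months, r.event)
               for r in grp]
        stat, p = logrank(grp, dup)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)


class TestCox:
    def test_null_covariate_recovers_hr_one(self, rng):
        n = 1000
        x = rng.normal(0, 1, n)
        t = rng.exponential(10, n)
        records = [rec(f"P{i}", float(ti), True, x=float(xi))
                   for i, (ti, xi) in enumerate(zip(t, x))]
        res = cox_fit(records, "x")
        assert res.ci95[0] < 1.0 < res.ci95[1]
        assert res.hazard_ratio == pytest.approx(1.0, abs=0.25)

    def test_partial_likelihood_matches_score_root_oracle(self):
        # 4 subjects, all events, no ties: the score equation has a finite
        # root computable independently
        xs = [1.0, 0.0, 0.0, 1.0]
        records = [rec(f"P{i}", float(i + 1), True, x=x)
                   for i, x in enumerate(xs)]

        def score(b):
            eb = np.exp(b)
            return ((1 - 2 * eb / (2 * eb + 2))
                    + (0 - eb / (eb + 2))
                    + (0 - eb / (1 + eb)))

        b_oracle = brentq(score, -5, 5)
        res = cox_fit(records, "x")
        assert np.log(res.hazard_ratio) == pytest.approx(b_oracle, abs=1e-4)

    def test_efron_tied_pair_gives_unit_hazard(self):
        records = [rec("A", 1.0, True, x=1.0), rec("B", 1.0, True, x=0.0),
                   rec("C", 2.0, False, x=1.0), rec("D", 2.0, False, x=0.0)]
        res = cox_fit(records, "x")
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)

    def test_log_linearity_under_covariate_rescaling(self, rng):
        n = 150
        x = rng.normal(0, 1, n)
        t = rng.exponential(1, n) / np.exp(0.4 * x)
        r1 = [rec(f"P{i}", float(ti), True, x=float(xi))
              for i, (ti, xi) in enumerate(zip(t, x))]
        r2 = [rec(f"P{i}", float(ti), True, x=float(2 * xi))
              for i, (ti, xi) in enumerate(zip(t, x))]
        b1 = np.log(cox_fit(r1, "x").hazard_ratio)
        b2 = np.log(cox_fit(r2, "x").hazard_ratio)
        assert b2 == pytest.approx(b1 / 2, rel=1e-4)

    def test_no_events_is_convergence_error(self):
        with pytest.raises(ConvergenceError):
            cox_fit([rec("A", 1.0, False, x=1.0)], "x")

    def test_time_varying_person_time_reconstruction(self):
        records = [rec("A", 10.0, True, switch=4.0),
                   rec("B", 8.0, False, switch=None),
                   rec("C", 6.0, True, switch=6.0),  # switch at the end
                   rec("D", 5.0, True, switch=2.0)]
        long = split_time_varying(records, "cleared")
        # interval lengths re-sum to each duration
        tot = long.assign(len=long.stop - long.start).groupby("patient_id")["len"].sum()
        assert tot["A"] == pytest.approx(10.0)
        assert tot["B"] == pytest.approx(8.0)
        # person-time before first clearance sits in the unexposed stratum
        unexposed = long[long.cleared == 0]
        assert unexposed.assign(len=long.stop - long.start)["len"].sum() == \
            pytest.approx(4.0 + 8.0 + 6.0 + 2.0)
        # events stay attached to the terminal interval
        assert long.groupby("patient_id")["event"].sum().tolist() == [1, 0, 1, 1]


class TestLandmark:
    def _records(self):
        return [rec("early_fail", 6.0, True, switch=3.0),
                rec("late_clear", 20.0, False, switch=14.0),
                rec("cleared", 30.0, False, switch=5.0),
                rec("cleared2", 25.0, True, switch=4.0),
                rec("never", 18.0, True),
                rec("never2", 30.0, True)]

    def test_pre_landmark_failure_excluded(self):
        lm = landmark_analysis(self._records(), 12.0)
        assert lm.n_exposed + lm.n_unexposed == 5  # early_fail dropped

    def test_late_clearance_grouped_as_uncleared_at_landmark(self):
        lm = landmark_analysis(self._records(), 12.0)
        assert lm.n_exposed == 2      # cleared, cleared2
        assert lm.n_unexposed == 3    # late_clear, never, never2

    def test_clock_restarts_at_landmark(self):
        lm = landmark_analysis(self._records(), 12.0)
        assert max(lm.km_unexposed.times) <= 18.01

    def test_empty_group_skipped(self):
        lm = landmark_analysis([rec("A", 20.0, True), rec("B", 25.0, False)],
                               12.0)
        assert lm.skipped is not None

    def test_landmark_attenuates_immortal_time_bias(self):
        # null-effect cohort with clearance only assignable at month 6:
        # naive ever-cleared grouping inherits immortal time, the landmark
        # estimate does not
        cohort, truth = generate(scenario(
            "null_effect", n_patients=400, seed=11,
            clearance_times_months=(6.0,)))
        trajs = classify_cohort(cohort)
        ttf, _ = build_endpoints(cohort)
        records = attach_switch_times(ttf, trajs, cohort)
        naive = [SurvivalRecord(r.patient_id, r.duration_months, r.event,
                                {"cleared": float(r.switch_time_months
                                                  is not None)})
                 for r in records]
        hr_naive = cox_fit(naive, "cleared").hazard_ratio
        lm = landmark_analysis(records, 12.0)
        assert hr_naive < 1.0
        assert lm.cox is not None
        assert hr_naive < lm.cox.hazard_ratio
        assert lm.cox.ci95[0] < 1.0 < lm.cox.ci95[1]


class TestFailureRates:
    def test_no_events_by_horizon_is_zero(self):
        records = [rec(f"P{i}", 30.0, False) for i in range(4)]
        out = failure_rate_at(records, {r.patient_id: "g" for r in records},
                              [12.0])
        assert out.loc[0, "failure_rate"] == pytest.approx(0.0)

    def test_all_fail_before_horizon_is_one(self):
        records = [rec(f"P{i}", float(i + 1), True) for i in range(4)]
        out = failure_rate_at(records, {r.patient_id: "g" for r in records},
                              [12.0])
        assert out.loc[0, "failure_rate"] == pytest.approx(1.0)

    def test_censored_mixture_hand_computed(self):
        records = [rec("A", 1, True), rec("B", 2, False), rec("C", 3, True),
                   rec("D", 4, False), rec("E", 5, True)]
        out = failure_rate_at(records, {r.patient_id: "g" for r in records},
                              [3.5, 6.0])
        # S(3.5) = 4/5 * 2/3 = 8/15
        assert out.loc[0, "failure_rate"] == pytest.approx(1 - 8 / 15)
        assert not out.loc[0, "beyond_followup"]
        assert bool(out.loc[1, "beyond_followup"])
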