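"""Plasma-imaging matching, exclusions, diagnostic performance, correlation."""

from __future__ import annotations

import numpy as np
import pytest

from ctdnamon.classify import classify_trajectory
from ctdnamon.concordance import (MatchedPair, RULES, apply_exclusions,
                                  best_response_correlation, evaluate_rule,
                                  match_pairs, retained_pairs)
from ctdnamon.pipeline import classify_cohort, matched_pairs_with_exclusions
from helpers import (START, build_cohort, day, patient_row, sample,
                     sample_row, scan_row)
from oracles import confusion_oracle, greedy_match_oracle, spearman_oracle


def mk_pair(call_positive: bool | None, prog: bool, *, pid="P1", d=100,
            measurable=True, excluded="none", pseudo=False,
            ratio=None) -> MatchedPair:
    """A matched pair whose call drives only the eVAF_50 relative rule."""
    bl = sample(pid, -3, 1.0)
    if call_positive is None:
        cur = sample(pid, d, None)
        sc = classify_trajectory([cur], START).per_sample[0]  # no baseline
    else:
        cur = sample(pid, d, 0.9 if call_positive else 0.01)
        traj = classify_trajectory([bl, cur], START)
        sc = traj.per_sample[-1]
    return MatchedPair(
        patient_id=pid, sample_date=day(d), scan_date=day(d), gap_days=0,
        sample_call=sc, radiologist_progression=prog, measurable=measurable,
        excluded=excluded != "none", exclusion_reason=excluded,
        bone_pseudoprogression=pseudo)


class TestMatching:
    def test_nearest_scan_within_window(self):
        m = match_pairs([day(100)], [day(95), day(140)], 30)
        assert m == [(0, 0, -5)]

    def test_outside_window_unmatched(self):
        assert match_pairs([day(100)], [day(131)], 30) == []

    def test_tie_broken_toward_earlier_scan(self):
        m = match_pairs([day(100)], [day(90), day(110)], 30)
        assert m == [(0, 0, -10)]

    def test_one_to_one(self):
        m = match_pairs([day(100), day(102)], [day(101)], 30)
        assert len(m) == 1
        assert m[0][0] == 0  # |gap| ties break toward the earlier sample

    def test_random_schedules_match_exhaustive_oracle(self, rng):
        for _ in range(50):
            ns, nc = int(rng.integers(0, 7)), int(rng.integers(0, 7))
            s_days = sorted(int(d) for d in rng.choice(400, ns, replace=False))
            c_days = sorted(int(d) for d in rng.choice(400, nc, replace=False))
            got = {(i, j) for i, j, _ in
                   match_pairs([day(d) for d in s_days],
                               [day(d) for d in c_days], 30)}
            assert got == greedy_match_oracle(s_days, c_days, 30)


class TestExclusions:
    def _traj(self, evafs, days):
        samples = [sample("P1", d, e) for d, e in zip(days, evafs)]
        return {"P1": classify_trajectory(samples, START)}

    def test_pseudoprogression_with_evaf_decrease_excluded(self):
        trajs = self._traj([1.0, 0.5], [-3, 100])
        pair = MatchedPair("P1", day(100), day(100), 0,
                           trajs["P1"].per_sample[-1], True,
                           bone_pseudoprogression=True)
        (out,) = apply_exclusions([pair], trajs)
        assert out.excluded and out.exclusion_reason == "pseudoprogression"

    def test_pseudoprogression_with_evaf_rise_retained(self):
        trajs = self._traj([1.0, 1.5], [-3, 100])
        pair = MatchedPair("P1", day(100), day(100), 0,
                           trajs["P1"].per_sample[-1], True,
                           bone_pseudoprogression=True)
        (out,) = apply_exclusions([pair], trajs)
        assert not out.excluded

    def test_baseline_undetected_excluded_from_relative_rules_only(self):
        samples = [sample("P1", -3, None), sample("P1", 100, 0.2)]
        trajs = {"P1": classify_trajectory(samples, START)}
        pair = MatchedPair("P1", day(100), day(100), 0,
                           trajs["P1"].per_sample[-1], False)
        (out,) = apply_exclusions([pair], trajs)
        assert out.exclusion_reason == "baseline_undetected"
        assert retained_pairs([out], RULES["evaf_50"]) == []
        # rise rules do not need the baseline; the pair may still count
        assert out not in retained_pairs([out], RULES["evaf_50"])


class TestEvaluateRule:
    def test_c_index_is_balanced_accuracy(self):
        # Se 0.80 (8/10), Sp 0.86 (43/50) -> C-index 0.83
        pairs = ([mk_pair(True, True, pid=f"A{i}") for i in range(8)]
                 + [mk_pair(False, True, pid=f"B{i}") for i in range(2)]
                 + [mk_pair(False, False, pid=f"C{i}") for i in range(43)]
                 + [mk_pair(True, False, pid=f"D{i}") for i in range(7)])
        perf = evaluate_rule(pairs, "evaf_50")
        assert perf.sensitivity == pytest.approx(0.80)
        assert perf.specificity == pytest.approx(0.86)
        assert perf.c_index == pytest.approx(0.83)

    def test_perfect_sensitivity_c_index(self):
        # Se 1.00 (10/10), Sp 0.74 (37/50) -> C-index 0.87
        pairs = ([mk_pair(True, True, pid=f"A{i}") for i in range(10)]
                 + [mk_pair(False, False, pid=f"C{i}") for i in range(37)]
                 + [mk_pair(True, False, pid=f"D{i}") for i in range(13)])
        perf = evaluate_rule(pairs, "evaf_50")
        assert perf.sensitivity == pytest.approx(1.0)
        assert perf.specificity == pytest.approx(0.74)
        assert perf.c_index == pytest.approx(0.87)

    def test_undefined_ratios_are_absent(self):
        pairs = [mk_pair(False, False), mk_pair(False, False, pid="P2")]
        perf = evaluate_rule(pairs, "evaf_50")
        assert perf.tp == 0 and perf.fp == 0
        assert perf.ppv is None
        assert perf.sensitivity is None  # no reference positives

    def test_counts_equal_brute_force_tally(self, rng):
        pairs, calls, refs = [], [], []
        for i in range(120):
            call = bool(rng.random() < 0.4)
            ref = bool(rng.random() < 0.3)
            pairs.append(mk_pair(call, ref, pid=f"P{i}"))
            calls.append(call)
            refs.append(ref)
        perf = evaluate_rule(pairs, "evaf_50")
        assert (perf.tp, perf.fp, perf.fn, perf.tn) == \
            confusion_oracle(calls, refs)
        assert perf.tp + perf.fp + perf.fn + perf.tn == len(pairs)

    def test_constant_negative_rule_has_half_c_index(self):
        pairs = [mk_pair(False, i < 3, pid=f"P{i}") for i in range(10)]
        perf = evaluate_rule(pairs, "evaf_50")
        assert perf.sensitivity == 0.0 and perf.specificity == 1.0
        assert perf.c_index == 0.5

    def test_tighter_abs_threshold_never_increases_positives(
            self, study_like, study_like_trajectories):
        from ctdnamon.classify import ClassificationConfig
        cohort, _ = study_like
        loose = matched_pairs_with_exclusions(cohort, classify_cohort(
            cohort, ClassificationConfig(abs_rise_threshold=0.01)))
        tight = matched_pairs_with_exclusions(cohort, classify_cohort(
            cohort, ClassificationConfig(abs_rise_threshold=0.05)))
        p_loose = evaluate_rule(loose, "rise_gt_0.01")
        p_tight = evaluate_rule(tight, "rise_gt_0.01")
        assert p_tight.tp + p_tight.fp <= p_loose.tp + p_loose.fp


class TestBestResponseCorrelation:
    def _cohort(self, d_evaf, d_diam):
        """n patients, each: baseline scan day 0, response scan day 100."""
        patients, samples, scans = [], [], []
        for i, (de, dd) in enumerate(zip(d_evaf, d_diam)):
            pid = f"P{i + 1}"
            patients.append(patient_row(pid))
            samples.append(sample_row(pid, -3, 1.0))
            samples.append(sample_row(pid, 100, max(1.0 + de, 1e-4)))
            scans.append(scan_row(pid, 0, target_mm=50.0))
            scans.append(scan_row(pid, 100, target_mm=max(50.0 * (1 + dd), 1.0)))
        return build_cohort(patients, samples, scans)

    def test_concordant_ranks_give_rho_one(self):
        deltas = [-0.9, -0.5, -0.1, 0.3]
        cohort = self._cohort(deltas, deltas)
        res = best_response_correlation(cohort, classify_cohort(cohort))
        assert res.rho == pytest.approx(1.0)
        assert res.n == 4

    def test_reversed_ranks_give_rho_minus_one(self):
        cohort = self._cohort([-0.9, -0.5, -0.1, 0.3],
                              [0.3, -0.1, -0.5, -0.9])
        res = best_response_correlation(cohort, classify_cohort(cohort))
        assert res.rho == pytest.approx(-1.0)

    def test_matches_closed_form_rank_formula(self, rng):
        de = rng.normal(-0.3, 0.4, 10)
        dd = 0.5 * de + rng.normal(0, 0.2, 10)
        cohort = self._cohort(de.tolist(), dd.tolist())
        res = best_response_correlation(cohort, classify_cohort(cohort))
        assert res.n == 10
        assert res.rho == pytest.approx(spearman_oracle(de, dd), abs=1e-9)

    def test_too_few_pairs_no_p_value(self):
        cohort = self._cohort([-0.5, -0.1], [-0.4, -0.2])
        res = best_response_correlation(cohort, classify_cohort(cohort))
        assert res.n == 2
        assert res.p_value is None
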