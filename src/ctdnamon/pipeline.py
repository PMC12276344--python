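"""Cohort-level orchestration: classify every patient, tabulate calls and
diagnostic performance, and assemble the standard rule grid."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .classify import (ClassificationConfig, TrajectoryClassification,
                       classify_trajectory)
from .cohort import BASELINE_WINDOW_DAYS, Cohort, samples_from_frame
from .concordance import (DEFAULT_MATCH_WINDOW_DAYS, MatchedPair,
                          apply_exclusions, build_matched_pairs, evaluate_rule)

__all__ = ["classify_cohort", "matched_pairs_with_exclusions",
           "per_sample_table", "trajectory_table", "performance_table",
           "STANDARD_RULE_GRID"]

#: The molecular-progression definitions evaluated against imaging.
STANDARD_RULE_GRID = ("any_rise", "rise_gt_0.01", "evaf_75", "evaf_50",
                      "evaf_25", "evaf_10", "combined")


def classify_cohort(cohort: Cohort,
                    config: ClassificationConfig = ClassificationConfig(),
                    baseline_window_days: int = BASELINE_WINDOW_DAYS,
                    baseline_grace_days: int = 0,
                    ) -> dict[str, TrajectoryClassification]:
    """Classify every patient with at least one non-failed sample."""
    out: dict[str, TrajectoryClassification] = {}
    for pid in cohort.patient_ids():
        samples = samples_from_frame(cohort.samples_for(pid))
        if not any(s.assay_status == "ok" for s in samples):
            continue
        start = cohort.patient_row(pid)["treatment_start"]
        out[pid] = classify_trajectory(
            samples, start, config,
            baseline_window_days=baseline_window_days,
            baseline_grace_days=baseline_grace_days)
    return out


def matched_pairs_with_exclusions(
        cohort: Cohort,
        trajectories: Mapping[str, TrajectoryClassification],
        window_days: int = DEFAULT_MATCH_WINDOW_DAYS) -> list[MatchedPair]:
    pairs = build_matched_pairs(cohort, trajectories, window_days)
    return apply_exclusions(pairs, trajectories)


def per_sample_table(trajectories: Mapping[str, TrajectoryClassification]
                     ) -> pd.DataFrame:
    rows = []
    for traj in trajectories.values():
        for c in traj.per_sample:
            row = {
                "patient_id": c.patient_id,
                "collection_date": c.collection_date,
                "is_baseline": c.is_baseline,
                "detected": c.detected,
                "evaf": c.evaf,
                "cleared": c.cleared,
                "ratio_to_baseline": c.ratio_to_baseline,
                "response_evaf_lt10": c.response_evaf_lt10,
                "rise_any": c.rise_any,
                "rise_gt_abs": c.rise_gt_abs,
                "combined_call": c.combined_call,
                "delta_from_prior": c.delta_from_prior,
            }
            if c.relative_calls is not None:
                for x, v in c.relative_calls.items():
                    row[f"evaf_{int(round(x * 100))}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def trajectory_table(trajectories: Mapping[str, TrajectoryClassification]
                     ) -> pd.DataFrame:
    rows = []
    for traj in trajectories.values():
        rows.append({
            "patient_id": traj.patient_id,
            "baseline_detected": traj.baseline_detected,
            "baseline_evaf": traj.baseline.evaf if traj.baseline else None,
            "ever_cleared": traj.ever_cleared,
            "first_clearance_date": traj.first_clearance_date,
            "consecutive_clearance": traj.consecutive_clearance,
            "ever_response_lt10": traj.ever_response_lt10,
            "first_response_date": traj.first_response_date,
            "last_response_date": traj.last_response_date,
            "early_decrease": traj.early_decrease,
            "early_rise": traj.early_rise,
        })
    return pd.DataFrame(rows)


def performance_table(pairs: Sequence[MatchedPair],
                      rules: Sequence[str] = STANDARD_RULE_GRID,
                      reference: str = "radiologist",
                      populations: Sequence[str] = ("measurable", "all"),
                      ) -> pd.DataFrame:
    """One row per rule x population: confusion counts and characteristics."""
    rows = []
    for rule in rules:
        for pop in populations:
            perf = evaluate_rule(pairs, rule, reference=reference,
                                 population=pop)
            rows.append({
                "rule": rule, "population": pop, "reference": reference,
                "n_pairs": perf.n_pairs,
                "tp": perf.tp, "fp": perf.fp, "fn": perf.fn, "tn": perf.tn,
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "ppv": perf.ppv, "npv": perf.npv,
                "accuracy": perf.accuracy, "c_index": perf.c_index,
                "flagged_fraction": perf.flagged_fraction,
            })
    return pd.DataFrame(rows)
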