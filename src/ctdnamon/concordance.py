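"""Plasma–imaging concordance: timepoint matching, exclusions, performance.

On-treatment plasma timepoints are matched one-to-one to restaging scans
within a ±30-day window (greedy nearest-gap, deterministic).  Against the
radiologist's progression adjudication (or RECIST v1.1 as a switch), each
molecular-progression rule is scored as a binary diagnostic test:
sensitivity, specificity, PPV, NPV, accuracy, and a C-index implemented as
balanced accuracy (Se + Sp)/2.

Exclusions mirror the monitoring analysis: scans with early bone
pseudoprogression are dropped when the matched sample shows an eVAF decrease
from baseline (new bone findings reflecting osteoblastic healing, not true
progression), and baseline-undetected patients are dropped from every
baseline-relative rule.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import SampleCall, TrajectoryClassification
from .cohort import Cohort

__all__ = [
    "Rule", "RULES", "MatchedPair", "DiagnosticPerformance",
    "CorrelationResult", "match_pairs", "build_matched_pairs",
    "apply_exclusions", "evaluate_rule", "best_response_correlation",
]

DEFAULT_MATCH_WINDOW_DAYS = 30


@dataclass(frozen=True)
class Rule:
    """A named molecular-progression (or response) rule over sample calls."""

    name: str
    extractor: Callable[[SampleCall], bool | None]
    needs_baseline: bool
    needs_prior: bool
    label: str


def _rel(threshold: float) -> Callable[[SampleCall], bool | None]:
    return lambda c: c.relative_call(threshold)


def _response(c: SampleCall) -> bool | None:
    if c.response_evaf_lt10 is None:
        return None
    return c.cleared or c.response_evaf_lt10


def _clearance(c: SampleCall) -> bool | None:
    # clearance is only defined for baseline-positive patients
    if c.ratio_to_baseline is None:
        return None
    return c.cleared


RULES: Mapping[str, Rule] = {r.name: r for r in [
    Rule("any_rise", lambda c: c.rise_any, False, True,
         "any eVAF rise from the immediate prior sample"),
    Rule("rise_gt_0.01", lambda c: c.rise_gt_abs, False, True,
         "eVAF rise >0.01 percentage points from the immediate prior sample"),
    Rule("evaf_75", _rel(0.75), True, False,
         "eVAF_75%: <25% decrease from baseline"),
    Rule("evaf_50", _rel(0.50), True, False,
         "eVAF_50%: <50% decrease from baseline"),
    Rule("evaf_25", _rel(0.25), True, False,
         "eVAF_25%: <75% decrease from baseline"),
    Rule("evaf_10", _rel(0.10), True, False,
         "eVAF_10%: <90% decrease from baseline"),
    Rule("combined", lambda c: c.combined_call, True, False,
         "rise >0.01 from prior and/or eVAF_50%"),
    Rule("molecular_response", _response, True, False,
         "molecular response: ctDNA clearance or eVAF_<10%"),
    Rule("clearance", _clearance, True, False,
         "ctDNA clearance (no ctDNA detected)"),
]}


@dataclass(frozen=True)
class MatchedPair:
    """A plasma timepoint joined to a restaging scan within the window."""

    patient_id: str
    sample_date: date
    scan_date: date
    gap_days: int  # scan_date - sample_date, signed
    sample_call: SampleCall
    radiologist_progression: bool
    recist_category: str | None = None
    target_lesion_sum_mm: float | None = None
    bone_pseudoprogression: bool = False
    measurable: bool = True
    excluded: bool = False
    exclusion_reason: str = "none"  # none | pseudoprogression | baseline_undetected

    def reference(self, which: str = "radiologist") -> bool:
        if which == "radiologist":
            return self.radiologist_progression
        if which == "recist":
            return self.recist_category == "PD"
        raise ValueError(f"unknown reference {which!r}")


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion counts and derived test characteristics for one rule.

    Undefined ratios (zero denominator) are ``None``, never 0.
    """

    rule_name: str
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    c_index: float | None
    flagged_fraction: float | None
    n_pairs: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float | None
    p_value: float | None
    n: int


def match_pairs(sample_dates: Sequence[date], scan_dates: Sequence[date],
                window_days: int = DEFAULT_MATCH_WINDOW_DAYS,
                ) -> list[tuple[int, int, int]]:
    """Greedy one-to-one matching of samples to scans by ascending |gap|.

    Returns ``(sample_index, scan_index, gap_days)`` triples with
    ``gap_days = scan - sample``.  Ties on |gap| are broken toward the
    earlier scan, then the earlier sample, so the matching is deterministic
    given its input.  Pairs beyond the window are discarded.
    """
    candidates = []
    for i, sd in enumerate(sample_dates):
        for j, cd in enumerate(scan_dates):
            gap = (cd - sd).days
            if abs(gap) <= window_days:
                candidates.append((abs(gap), cd, sd, i, j, gap))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_s: set[int] = set()
    used_c: set[int] = set()
    out = []
    for _, _, _, i, j, gap in candidates:
        if i in used_s or j in used_c:
            continue
        used_s.add(i)
        used_c.add(j)
        out.append((i, j, gap))
    out.sort()
    return out


def build_matched_pairs(cohort: Cohort,
                        trajectories: Mapping[str, TrajectoryClassification],
                        window_days: int = DEFAULT_MATCH_WINDOW_DAYS,
                        ) -> list[MatchedPair]:
    """Match each patient's on-treatment sample calls to on-treatment scans.

    Baseline staging scans (scan date on or before treatment start) and the
    baseline plasma draw are excluded: concordance is an on-treatment
    analysis.
    """
    pairs: list[MatchedPair] = []
    for pid, traj in trajectories.items():
        row = cohort.patient_row(pid)
        start = row["treatment_start"]
        calls = [c for c in traj.per_sample
                 if not c.is_baseline and c.collection_date > start]
        scans = [s for _, s in cohort.scans_for(pid).iterrows()
                 if s["scan_date"] > start]
        matches = match_pairs([c.collection_date for c in calls],
                              [s["scan_date"] for s in scans], window_days)
        for i, j, gap in matches:
            s = scans[j]
            pairs.append(MatchedPair(
                patient_id=pid,
                sample_date=calls[i].collection_date,
                scan_date=s["scan_date"],
                gap_days=gap,
                sample_call=calls[i],
                radiologist_progression=bool(s["radiologist_progression"]),
                recist_category=s["recist_category"],
                target_lesion_sum_mm=s["target_lesion_sum_mm"],
                bone_pseudoprogression=bool(s["bone_pseudoprogression"]),
                measurable=bool(row["measurable_disease"]),
            ))
    return pairs


def apply_exclusions(pairs: Sequence[MatchedPair],
                     trajectories: Mapping[str, TrajectoryClassification],
                     ) -> list[MatchedPair]:
    """Flag the monitoring-analysis exclusions on matched pairs.

    * bone-pseudoprogression scans where the matched sample shows an eVAF
      decrease from baseline → excluded for every rule;
    * pairs from baseline-undetected patients → excluded for
      baseline-relative rules only (their baseline-relative calls are
      undefined anyway).
    """
    out = []
    for p in pairs:
        traj = trajectories[p.patient_id]
        if (p.bone_pseudoprogression
                and p.sample_call.ratio_to_baseline is not None
                and p.sample_call.ratio_to_baseline < 1.0):
            out.append(replace(p, excluded=True,
                               exclusion_reason="pseudoprogression"))
        elif not traj.baseline_detected:
            out.append(replace(p, excluded=True,
                               exclusion_reason="baseline_undetected"))
        else:
            out.append(p)
    return out


def retained_pairs(pairs: Sequence[MatchedPair], rule: Rule) -> list[MatchedPair]:
    """Pairs entering a rule's denominator after exclusions."""
    kept = []
    for p in pairs:
        if p.exclusion_reason == "pseudoprogression":
            continue
        if p.exclusion_reason == "baseline_undetected" and rule.needs_baseline:
            continue
        if rule.extractor(p.sample_call) is None:
            continue
        kept.append(p)
    return kept


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def evaluate_rule(pairs: Sequence[MatchedPair], rule_name: str,
                  reference: str = "radiologist",
                  population: str = "all") -> DiagnosticPerformance:
    """Score a molecular rule against radiographic progression.

    ``population`` restricts to RECIST-measurable patients (``"measurable"``)
    or uses the complete cohort (``"all"``).  The C-index of a binary rule is
    balanced accuracy, (Se + Sp)/2.
    """
    if population not in {"all", "measurable"}:
        raise ValueError(f"unknown population {population!r}")
    rule = RULES[rule_name]
    kept = retained_pairs(pairs, rule)
    if population == "measurable":
        kept = [p for p in kept if p.measurable]
    tp = fp = fn = tn = 0
    for p in kept:
        call = bool(rule.extractor(p.sample_call))
        ref = p.reference(reference)
        if call and ref:
            tp += 1
        elif call and not ref:
            fp += 1
        elif not call and ref:
            fn += 1
        else:
            tn += 1
    se = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    total = tp + fp + fn + tn
    return DiagnosticPerformance(
        rule_name=rule_name, tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=se, specificity=sp,
        ppv=_ratio(tp, tp + fp), npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, total),
        c_index=(se + sp) / 2 if se is not None and sp is not None else None,
        flagged_fraction=_ratio(tp + fp, total),
        n_pairs=total,
    )


def best_response_correlation(cohort: Cohort,
                              trajectories: Mapping[str, TrajectoryClassification],
                              window_days: int = DEFAULT_MATCH_WINDOW_DAYS,
                              ) -> CorrelationResult:
    """Spearman correlation of ΔeVAF and Δdiameters at best response.

    For each measurable-disease patient with a detected baseline eVAF and a
    baseline target-lesion sum: Δdiameter is the percent change from the
    baseline staging scan to the on-treatment scan with the smallest
    target-lesion sum (best response); ΔeVAF is the percent change from
    baseline eVAF at the plasma sample nearest that scan (within the
    matching window).
    """
    d_evaf, d_diam = [], []
    for pid, traj in trajectories.items():
        if not traj.baseline_detected:
            continue
        row = cohort.patient_row(pid)
        if not bool(row["measurable_disease"]):
            continue
        start = row["treatment_start"]
        scans = cohort.scans_for(pid)
        base_scans = [s for _, s in scans.iterrows()
                      if s["scan_date"] <= start
                      and s["target_lesion_sum_mm"] is not None]
        on_scans = [s for _, s in scans.iterrows()
                    if s["scan_date"] > start
                    and s["target_lesion_sum_mm"] is not None]
        if not base_scans or not on_scans:
            continue
        d0 = base_scans[-1]["target_lesion_sum_mm"]
        best = min(on_scans, key=lambda s: s["target_lesion_sum_mm"])
        calls = [c for c in traj.per_sample if not c.is_baseline
                 and c.collection_date > start]
        if not calls or d0 <= 0:
            continue
        nearest = min(calls,
                      key=lambda c: abs((c.collection_date - best["scan_date"]).days))
        if abs((nearest.collection_date - best["scan_date"]).days) > window_days:
            continue
        evaf = nearest.evaf if nearest.detected and nearest.evaf else 0.0
        bl = traj.baseline.evaf  # type: ignore[union-attr]
        d_evaf.append(100.0 * (evaf - bl) / bl)
        d_diam.append(100.0 * (best["target_lesion_sum_mm"] - d0) / d0)
    n = len(d_evaf)
    if n < 2:
        return CorrelationResult(rho=None, p_value=None, n=n)
    rho, p = stats.spearmanr(d_evaf, d_diam)
    return CorrelationResult(rho=float(rho), p_value=float(p) if n >= 3 else None,
                             n=n)
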