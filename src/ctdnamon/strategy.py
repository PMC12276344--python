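"""Lead times and plasma-first follow-up policy simulation.

A plasma-first policy skips a scheduled restaging scan when the temporally
matched plasma sample meets a molecular *response* rule (e.g. ctDNA
clearance or eVAF_<10%), and can force an unscheduled scan when a *trigger*
rule (e.g. eVAF_75%) fires.  Two evaluation modes:

* **retrospective** (default) — walks the matched plasma/scan pairs that were
  actually observed, counting how many performed scans the policy would have
  avoided, how many radiographic progressions would have been missed at
  their matched scan, and the delay to the next performed scan for each
  missed progression.  This is the mode whose avoided fraction is directly
  interpretable against an observed cohort.
* **forward** — walks each patient's calendar: every scheduled scan is
  skipped when a sample within the matching window meets the response rule;
  trigger-positive samples with no scan within the window force one.

Detection delay for a skipped progression is measured to the next performed
or triggered scan and is a model-derived quantity (no observed counterpart).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import numpy as np

from .classify import TrajectoryClassification
from .cohort import Cohort, months_between
from .concordance import RULES, DEFAULT_MATCH_WINDOW_DAYS, MatchedPair

__all__ = [
    "LeadTime", "Policy", "PolicyOutcome", "compute_lead_times",
    "lead_time_summary", "simulate_policy",
]

ANCHORS = ("last_cleared", "last_response", "first_progression_call")


@dataclass(frozen=True)
class LeadTime:
    """Interval from a qualifying plasma anchor to failure/last follow-up."""

    patient_id: str
    anchor: str
    anchor_date: date
    reference: str  # treatment_failure | last_followup
    reference_date: date
    lead_months: float


@dataclass(frozen=True)
class Policy:
    """A plasma-first follow-up policy.

    response_rule / trigger_rule are names from
    :data:`ctdnamon.concordance.RULES`; trigger_rule may be ``None``.
    """

    name: str
    response_rule: str = "molecular_response"
    trigger_rule: str | None = None
    mode: str = "retrospective"  # retrospective | forward

    def __post_init__(self) -> None:
        if self.response_rule not in RULES:
            raise ValueError(f"unknown response rule {self.response_rule!r}; "
                             f"known: {sorted(RULES)}")
        if self.trigger_rule is not None and self.trigger_rule not in RULES:
            raise ValueError(f"unknown trigger rule {self.trigger_rule!r}")
        if self.mode not in {"retrospective", "forward"}:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PolicyOutcome:
    policy_name: str
    n_scans_scheduled: int
    n_scans_avoided: int
    avoided_fraction: float | None
    n_patients: int
    n_patients_with_avoided: int
    n_progressions: int
    n_missed_at_matched_scan: int
    n_triggered_scans: int
    median_detection_delay_months: float | None


def _anchor_date(traj: TrajectoryClassification, anchor: str,
                 progression_rule: str = "combined") -> date | None:
    if anchor == "last_cleared":
        cleared = [c.collection_date for c in traj.per_sample
                   if not c.is_baseline and c.cleared and traj.baseline_detected]
        return cleared[-1] if cleared else None
    if anchor == "last_response":
        return traj.last_response_date
    if anchor == "first_progression_call":
        extract = RULES[progression_rule].extractor
        pos = [c.collection_date for c in traj.per_sample
               if not c.is_baseline and bool(extract(c))]
        return pos[0] if pos else None
    raise ValueError(f"unknown anchor {anchor!r}; known: {ANCHORS}")


def compute_lead_times(trajectories: Mapping[str, TrajectoryClassification],
                       cohort: Cohort, anchor: str,
                       progression_rule: str = "combined") -> list[LeadTime]:
    """One lead-time record per patient with a resolvable anchor.

    The reference is the treatment-failure date for patients with a failure
    event, otherwise the last follow-up.  Negative leads (anchor after the
    reference) are retained; the sign carries the information.
    """
    out = []
    for pid, traj in trajectories.items():
        a_date = _anchor_date(traj, anchor, progression_rule)
        if a_date is None:
            continue
        p = cohort.patient_row(pid)
        if bool(p["failure_event"]) and p["treatment_end"] is not None:
            ref_name, ref_date = "treatment_failure", p["treatment_end"]
        else:
            ref_name, ref_date = "last_followup", p["last_followup"]
        out.append(LeadTime(
            patient_id=pid, anchor=anchor, anchor_date=a_date,
            reference=ref_name, reference_date=ref_date,
            lead_months=months_between(ref_date, a_date)))
    return out


def lead_time_summary(leads: Sequence[LeadTime]) -> dict:
    """Median and IQR of lead times in months."""
    if not leads:
        return {"n": 0, "median": None, "iqr": (None, None)}
    vals = np.array([lt.lead_months for lt in leads])
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"n": len(vals), "median": float(med),
            "iqr": (float(q1), float(q3))}


def simulate_policy(pairs: Sequence[MatchedPair], policy: Policy,
                    *, reference: str = "radiologist") -> PolicyOutcome:
    """Retrospective policy evaluation over matched plasma/scan pairs.

    Every matched, non-excluded scan is a scheduled scan.  It is avoided
    when its matched sample meets the response rule; a trigger-rule-positive
    sample always forces its scan to be performed (trigger overrides skip).
    Missed progressions are reference-progressive scans that were skipped;
    their detection delay runs to the patient's next performed scan.
    """
    if policy.mode != "retrospective":
        raise ValueError("simulate_policy evaluates retrospective policies; "
                         "use simulate_policy_forward for forward mode")
    resp = RULES[policy.response_rule]
    trig = RULES[policy.trigger_rule] if policy.trigger_rule else None

    usable = [p for p in pairs if p.exclusion_reason != "pseudoprogression"]
    by_patient: dict[str, list[MatchedPair]] = {}
    for p in usable:
        by_patient.setdefault(p.patient_id, []).append(p)

    scheduled = avoided = missed = triggered = progressions = 0
    patients_with_avoided: set[str] = set()
    delays: list[float] = []
    for pid, plist in by_patient.items():
        plist = sorted(plist, key=lambda p: p.scan_date)
        performed_dates = []
        skipped_prog: list[date] = []
        for p in plist:
            scheduled += 1
            is_prog = p.reference(reference)
            progressions += int(is_prog)
            resp_call = resp.extractor(p.sample_call)
            trig_call = trig.extractor(p.sample_call) if trig else None
            skip = bool(resp_call)
            if trig_call:
                triggered += 1
                skip = False
            if skip:
                avoided += 1
                patients_with_avoided.add(pid)
                if is_prog:
                    missed += 1
                    skipped_prog.append(p.scan_date)
            else:
                performed_dates.append(p.scan_date)
        for d in skipped_prog:
            later = [pd_ for pd_ in performed_dates if pd_ > d]
            if later:
                delays.append(months_between(min(later), d))
    return PolicyOutcome(
        policy_name=policy.name,
        n_scans_scheduled=scheduled,
        n_scans_avoided=avoided,
        avoided_fraction=avoided / scheduled if scheduled else None,
        n_patients=len(by_patient),
        n_patients_with_avoided=len(patients_with_avoided),
        n_progressions=progressions,
        n_missed_at_matched_scan=missed,
        n_triggered_scans=triggered,
        median_detection_delay_months=float(np.median(delays)) if delays else None,
    )


def simulate_policy_forward(cohort: Cohort,
                            trajectories: Mapping[str, TrajectoryClassification],
                            policy: Policy,
                            window_days: int = DEFAULT_MATCH_WINDOW_DAYS,
                            *, reference: str = "radiologist") -> PolicyOutcome:
    """Forward-walking policy simulation over the full cohort calendar.

    Scheduled scans come from the imaging table; each is skipped when a
    non-baseline sample within the window meets the response rule.  A
    trigger-positive sample with no scan inside the window forces an extra
    (triggered) scan at the sample date.
    """
    resp = RULES[policy.response_rule]
    trig = RULES[policy.trigger_rule] if policy.trigger_rule else None

    scheduled = avoided = missed = triggered = progressions = 0
    patients_with_avoided: set[str] = set()
    delays: list[float] = []
    for pid, traj in trajectories.items():
        start = cohort.patient_row(pid)["treatment_start"]
        scans = [s for _, s in cohort.scans_for(pid).iterrows()
                 if s["scan_date"] > start]
        calls = [c for c in traj.per_sample
                 if not c.is_baseline and c.collection_date > start]
        performed: list[date] = []
        skipped_prog: list[date] = []
        for s in scans:
            scheduled += 1
            is_prog = (bool(s["radiologist_progression"]) if reference ==
                       "radiologist" else s["recist_category"] == "PD")
            progressions += int(is_prog)
            near = [c for c in calls
                    if abs((c.collection_date - s["scan_date"]).days)
                    <= window_days]
            skip = any(bool(resp.extractor(c)) for c in near) and near != []
            if trig and any(bool(trig.extractor(c)) for c in near):
                skip = False
            if skip:
                avoided += 1
                patients_with_avoided.add(pid)
                if is_prog:
                    missed += 1
                    skipped_prog.append(s["scan_date"])
            else:
                performed.append(s["scan_date"])
        if trig:
            scan_dates = [s["scan_date"] for s in scans]
            for c in calls:
                if bool(trig.extractor(c)) and not any(
                        abs((c.collection_date - d).days) <= window_days
                        for d in scan_dates):
                    triggered += 1
                    performed.append(c.collection_date)
        for d in skipped_prog:
            later = [pd_ for pd_ in performed if pd_ > d]
            if later:
                delays.append(months_between(min(later), d))
    return PolicyOutcome(
        policy_name=policy.name,
        n_scans_scheduled=scheduled,
        n_scans_avoided=avoided,
        avoided_fraction=avoided / scheduled if scheduled else None,
        n_patients=len(trajectories),
        n_patients_with_avoided=len(patients_with_avoided),
        n_progressions=progressions,
        n_missed_at_matched_scan=missed,
        n_triggered_scans=triggered,
        median_detection_delay_months=float(np.median(delays)) if delays else None,
    )
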