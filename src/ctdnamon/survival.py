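"""Survival endpoints and analyses: KM, log-rank, Cox, time-varying, landmark.

Endpoints follow the monitoring study's definitions:

* **TTF** (time to treatment failure) — treatment start to discontinuation of
  *both* the endocrine agent and the CDK4/6 inhibitor for any reason;
  censored at last follow-up otherwise.
* **OS** — treatment start to death of any cause; censored at last follow-up.

Estimation is delegated to lifelines (Kaplan–Meier product-limit estimator,
Mantel log-rank test, Cox partial likelihood with Efron tie handling, and a
time-varying Cox model where a binary covariate such as ctDNA clearance
switches from 0 to 1 at a per-patient time).  The landmark construct guards
against immortal-time bias: patients event-free at the landmark are grouped
by their status *as of* the landmark and the clock restarts there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .classify import TrajectoryClassification
from .cohort import Cohort, months_between

__all__ = [
    "SurvivalRecord", "CoxResult", "KMEstimate", "build_endpoints",
    "records_frame", "km_fit", "logrank", "cox_fit", "attach_switch_times",
    "landmark_analysis", "failure_rate_at",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Per-patient duration/event with optional covariates and switch time."""

    patient_id: str
    duration_months: float
    event: bool
    covariates: Mapping[str, float] | None = None
    switch_time_months: float | None = None

    def __post_init__(self) -> None:
        if self.duration_months < 0:
            raise ValueError(f"{self.patient_id}: negative duration")
        if (self.switch_time_months is not None
                and self.switch_time_months > self.duration_months):
            raise ValueError(f"{self.patient_id}: switch time after duration")


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n_events: int
    covariate: str


@dataclass(frozen=True)
class KMEstimate:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        """Step-function value of the product-limit estimate at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


class ConvergenceError(RuntimeError):
    """Cox fit failed (no events, complete separation, or non-convergence)."""


def build_endpoints(cohort: Cohort) -> tuple[list[SurvivalRecord], list[SurvivalRecord]]:
    """Construct (TTF, OS) record lists from the patients table.

    A TTF event requires the failure flag (both agents stopped); patients
    still on treatment are censored at last follow-up.  Death of any cause is
    the OS event.  Negative durations raise naming the patient.
    """
    ttf, os_ = [], []
    for _, p in cohort.patients.iterrows():
        pid = p["patient_id"]
        start = p["treatment_start"]
        failed = bool(p["failure_event"])
        end = p["treatment_end"] if failed and p["treatment_end"] is not None \
            else p["last_followup"]
        try:
            ttf.append(SurvivalRecord(pid, months_between(end, start), failed))
        except ValueError as exc:
            raise ValueError(f"TTF endpoint: {exc}") from exc
        died = p["death_date"] is not None
        oend = p["death_date"] if died else p["last_followup"]
        try:
            os_.append(SurvivalRecord(pid, months_between(oend, start), died))
        except ValueError as exc:
            raise ValueError(f"OS endpoint: {exc}") from exc
    return ttf, os_


def records_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    half_day = 0.5 / 30.4375
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id,
               "duration": max(r.duration_months, half_day),
               "event": int(r.event), "switch_time": r.switch_time_months}
        if r.covariates:
            row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def km_fit(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan–Meier product-limit estimate with at-risk counts and median."""
    df = records_frame(records)
    kmf = KaplanMeierFitter()
    kmf.fit(df["duration"], df["event"])
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    median = kmf.median_survival_time_
    return KMEstimate(times=times, survival=surv, at_risk=at_risk,
                      median=None if np.isinf(median) else float(median))


def logrank(group_a: Sequence[SurvivalRecord],
            group_b: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Mantel log-rank test (1 df): returns (chi-square statistic, p)."""
    a, b = records_frame(group_a), records_frame(group_b)
    res = _ll_logrank(a["duration"], b["duration"], a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


def _wald_result(model, covariate: str, n_events: int) -> CoxResult:
    hr = float(np.exp(model.params_[covariate]))
    ci = model.confidence_intervals_
    low, high = float(np.exp(ci.loc[covariate].iloc[0])), \
        float(np.exp(ci.loc[covariate].iloc[1]))
    p = float(model.summary.loc[covariate, "p"])
    return CoxResult(hazard_ratio=hr, ci95=(low, high), p_value=p,
                     n_events=n_events, covariate=covariate)


def cox_fit(records: Sequence[SurvivalRecord], covariate: str,
            adjust_for: Sequence[str] = (), *,
            time_varying: bool = False) -> CoxResult:
    """Cox proportional-hazards fit for one covariate of interest.

    In fixed mode ``covariate`` (and any adjustment covariates) must be keys
    of each record's ``covariates`` map.  In time-varying mode the covariate
    is the binary exposure switching 0→1 at ``switch_time_months`` (absent
    switch = never exposed); each record is split into pre/post intervals so
    person-time before the switch counts as unexposed.  Efron tie handling;
    Wald intervals and p-values.
    """
    df = records_frame(records)
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ConvergenceError("no events: Cox model is unidentifiable")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if time_varying:
                long = split_time_varying(records, covariate)
                ctv = CoxTimeVaryingFitter()
                ctv.fit(long[["patient_id", "start", "stop", "event", covariate]
                             + list(adjust_for)],
                        id_col="patient_id", start_col="start",
                        stop_col="stop", event_col="event")
                return _wald_result(ctv, covariate, n_events)
            cph = CoxPHFitter()
            cph.fit(df[["duration", "event", covariate] + list(adjust_for)],
                    duration_col="duration", event_col="event")
            return _wald_result(cph, covariate, n_events)
    except ConvergenceError:
        raise
    except Exception as exc:  # lifelines raises several convergence types
        raise ConvergenceError(f"Cox fit failed: {exc}") from exc


def split_time_varying(records: Sequence[SurvivalRecord],
                       covariate: str) -> pd.DataFrame:
    """Long-format (start, stop] interval table for the time-varying model.

    A record with switch time *s* < duration *d* becomes an unexposed
    interval (0, s] and an exposed interval (s, d] carrying the event; a
    record without a switch (or with s ≥ d) is a single unexposed interval.
    """
    half_day = 0.5 / 30.4375
    rows = []
    for r in records:
        s = r.switch_time_months
        extra = dict(r.covariates or {})
        # zero-length at-risk intervals are degenerate for the partial
        # likelihood; clamp to half a day
        dur = max(r.duration_months, half_day)
        if s is not None and 0 < s < dur:
            rows.append({"patient_id": r.patient_id, "start": 0.0, "stop": s,
                         "event": 0, covariate: 0, **extra})
            rows.append({"patient_id": r.patient_id, "start": s,
                         "stop": dur, "event": int(r.event),
                         covariate: 1, **extra})
        else:
            exposed = int(s is not None and s <= 0)
            rows.append({"patient_id": r.patient_id, "start": 0.0,
                         "stop": dur, "event": int(r.event),
                         covariate: exposed, **extra})
    return pd.DataFrame(rows)


def attach_switch_times(records: Sequence[SurvivalRecord],
                        trajectories: Mapping[str, TrajectoryClassification],
                        cohort: Cohort) -> list[SurvivalRecord]:
    """Set each record's switch time to the first ctDNA clearance.

    Clearance after the endpoint duration (e.g. at the failure visit) leaves
    the record unexposed.
    """
    out = []
    for r in records:
        traj = trajectories.get(r.patient_id)
        switch = None
        if traj is not None and traj.first_clearance_date is not None:
            start = cohort.patient_row(r.patient_id)["treatment_start"]
            t = months_between(traj.first_clearance_date, start)
            if 0 < t <= r.duration_months:
                switch = t
        out.append(SurvivalRecord(r.patient_id, r.duration_months, r.event,
                                  r.covariates, switch))
    return out


@dataclass
class LandmarkResult:
    landmark_months: float
    n_exposed: int
    n_unexposed: int
    km_exposed: KMEstimate | None
    km_unexposed: KMEstimate | None
    cox: CoxResult | None
    skipped: str | None = None


def landmark_analysis(records: Sequence[SurvivalRecord],
                      landmark_months: float) -> LandmarkResult:
    """Landmark analysis: restrict to patients event-free and under follow-up
    at the landmark, group by exposure status (switch time ≤ landmark), and
    restart the clock at the landmark.
    """
    if landmark_months <= 0:
        raise ValueError("landmark_months must be > 0")
    at_risk = [r for r in records if r.duration_months > landmark_months]
    exposed, unexposed = [], []
    for r in at_risk:
        grp = (r.switch_time_months is not None
               and r.switch_time_months <= landmark_months)
        rec = SurvivalRecord(r.patient_id,
                             r.duration_months - landmark_months,
                             r.event, r.covariates,
                             None)
        (exposed if grp else unexposed).append(rec)
    if not exposed or not unexposed:
        return LandmarkResult(landmark_months, len(exposed), len(unexposed),
                              None, None, None,
                              skipped="empty group at the landmark")
    combined = [SurvivalRecord(r.patient_id, r.duration_months, r.event,
                               {"exposed": 1.0}, None) for r in exposed] + \
               [SurvivalRecord(r.patient_id, r.duration_months, r.event,
                               {"exposed": 0.0}, None) for r in unexposed]
    try:
        cox = cox_fit(combined, "exposed")
    except ConvergenceError:
        cox = None
    return LandmarkResult(landmark_months, len(exposed), len(unexposed),
                          km_fit(exposed), km_fit(unexposed), cox)


def failure_rate_at(records: Sequence[SurvivalRecord],
                    group_labels: Mapping[str, str],
                    horizons: Sequence[float]) -> pd.DataFrame:
    """Per-group cumulative failure proportions, 1 − KM(t), at each horizon.

    ``group_labels`` maps patient_id → group name.  A horizon beyond a
    group's last observed time reports the value at the last time and is
    flagged ``beyond_followup``.
    """
    rows = []
    groups: dict[str, list[SurvivalRecord]] = {}
    for r in records:
        groups.setdefault(group_labels[r.patient_id], []).append(r)
    for name in sorted(groups):
        km = km_fit(groups[name])
        last = max(r.duration_months for r in groups[name])
        for h in horizons:
            rows.append({
                "group": name, "horizon_months": h,
                "failure_rate": 1.0 - km.survival_at(min(h, last)),
                "beyond_followup": h > last,
                "n": len(groups[name]),
            })
    return pd.DataFrame(rows)
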