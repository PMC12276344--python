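"""Molecular response and progression calls from serial eVAF measurements.

Per-sample calls (relative to the baseline draw and the immediate prior
non-failed sample):

* **clearance** — no ctDNA detected on treatment in a baseline-positive
  patient (complete molecular response, subject to the assay LoD).
* **eVAF_<10%** — molecular response: eVAF reduced by *more than* 90% from
  baseline (ratio to baseline < 0.10).
* **eVAF_75/50/25/10%** — molecular progression at graded stringency: absence
  of decrease or a decrease of less than 25/50/75/90% from baseline, i.e. the
  retained fraction of baseline eVAF is at or above 0.75/0.50/0.25/0.10.
* **any rise / rise > 0.01** — eVAF increase from the immediate prior sample,
  optionally requiring the absolute increment to exceed 0.01 percentage
  points to damp technical noise.
* **combined** — rise > 0.01 from prior OR eVAF_50% (the highest-accuracy
  combination of absolute and relative dynamics).

Boundary convention: a reduction of exactly 90% is eVAF_10%-positive and
response-negative (response requires ratio strictly below 0.10), so the two
calls are mutually exclusive and jointly exhaustive.  Undetected on-treatment
samples are treated as eVAF 0 in ratios and deltas, which keeps rise
detection after clearance well-defined (a redetection after clearance is a
rise).  Failed samples are skipped when finding the immediate prior sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Mapping, Sequence

from .cohort import (BASELINE_WINDOW_DAYS, PlasmaSample, derive_baseline)

__all__ = [
    "ClassificationConfig", "SampleCall", "TrajectoryClassification",
    "call_sample", "classify_trajectory",
]


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds and windows for molecular response/progression calls.

    abs_rise_threshold
        minimum eVAF increment from the prior sample, in percentage points,
        for the noise-controlled rise call (default 0.01).
    relative_grid
        retained-fraction thresholds for the graded progression calls
        (default 0.75, 0.50, 0.25, 0.10 — eVAF_75% down to eVAF_10%).
    response_reduction
        fractional reduction from baseline defining molecular response
        (default 0.90, i.e. eVAF_<10%: ratio to baseline < 0.10).
    early_decrease_window_days / early_rise_window_days
        windows after treatment start for early-kinetics flags (28 d — the
        first treatment cycle — and 29 d respectively; both are parameters
        because they describe different early-kinetics observations).
    consecutive_clearance_n
        number of successive cleared on-treatment samples for the
        consecutive-clearance flag (default 2).
    """

    abs_rise_threshold: float = 0.01
    relative_grid: tuple[float, ...] = (0.75, 0.50, 0.25, 0.10)
    response_reduction: float = 0.90
    early_decrease_window_days: int = 28
    early_rise_window_days: int = 29
    consecutive_clearance_n: int = 2

    def __post_init__(self) -> None:
        for x in self.relative_grid:
            if not 0 < x < 1:
                raise ValueError("relative_grid thresholds must lie in (0, 1)")
        if not 0 < self.response_reduction < 1:
            raise ValueError("response_reduction must lie in (0, 1)")
        if self.early_decrease_window_days <= 0 or self.early_rise_window_days <= 0:
            raise ValueError("windows must be positive")


@dataclass(frozen=True)
class SampleCall:
    """Molecular calls for one non-failed plasma sample.

    Baseline-relative fields are ``None`` for baseline-undetected patients;
    rise fields are ``None`` for the baseline sample itself or when no prior
    sample exists.
    """

    patient_id: str
    collection_date: date
    detected: bool
    evaf: float | None
    is_baseline: bool
    cleared: bool
    ratio_to_baseline: float | None = None
    response_evaf_lt10: bool | None = None
    relative_calls: Mapping[float, bool] | None = None
    rise_any: bool | None = None
    rise_gt_abs: bool | None = None
    combined_call: bool | None = None
    delta_from_prior: float | None = None

    def relative_call(self, threshold: float) -> bool | None:
        if self.relative_calls is None:
            return None
        return self.relative_calls[threshold]


@dataclass
class TrajectoryClassification:
    """Per-patient molecular trajectory summary."""

    patient_id: str
    baseline: PlasmaSample | None
    baseline_detected: bool
    excluded_from_relative_metrics: bool
    per_sample: list[SampleCall] = field(default_factory=list)
    ever_cleared: bool | None = None
    first_clearance_date: date | None = None
    consecutive_clearance: bool | None = None
    ever_response_lt10: bool | None = None
    first_response_date: date | None = None
    last_response_date: date | None = None
    early_decrease: bool | None = None
    early_rise: bool | None = None


def _effective_evaf(sample: PlasmaSample) -> float:
    """eVAF for arithmetic: undetected non-failed samples count as 0."""
    return sample.evaf if (sample.detected and sample.evaf is not None) else 0.0


def call_sample(current: PlasmaSample,
                prior: PlasmaSample | None,
                baseline: PlasmaSample | None,
                config: ClassificationConfig = ClassificationConfig(),
                *, is_baseline: bool = False) -> SampleCall:
    """Evaluate all molecular rules for one non-failed sample.

    ``prior`` must be the nearest earlier non-failed sample (failed samples
    skipped); ``baseline`` the patient's baseline draw.  Baseline-relative
    fields require a detected baseline; rise fields require a prior and are
    never computed for the baseline sample itself.
    """
    if current.assay_status != "ok":
        raise ValueError("call_sample requires a non-failed sample")
    cur = _effective_evaf(current)
    cleared = not current.detected

    ratio = response = None
    relative: dict[float, bool] | None = None
    if baseline is not None and baseline.detected and baseline.evaf:
        ratio = cur / baseline.evaf
        response = ratio < (1.0 - config.response_reduction)
        relative = {x: ratio >= x for x in config.relative_grid}

    rise_any = rise_abs = delta = None
    if prior is not None and not is_baseline:
        delta = cur - _effective_evaf(prior)
        rise_any = delta > 0
        rise_abs = delta > config.abs_rise_threshold

    combined = None
    if relative is not None and not is_baseline and 0.50 in relative:
        combined = bool(rise_abs) or relative[0.50]

    return SampleCall(
        patient_id=current.patient_id,
        collection_date=current.collection_date,
        detected=current.detected,
        evaf=current.evaf,
        is_baseline=is_baseline,
        cleared=cleared,
        ratio_to_baseline=ratio,
        response_evaf_lt10=response,
        relative_calls=relative,
        rise_any=rise_any,
        rise_gt_abs=rise_abs,
        combined_call=combined,
        delta_from_prior=delta,
    )


def classify_trajectory(samples: Sequence[PlasmaSample],
                        treatment_start: date,
                        config: ClassificationConfig = ClassificationConfig(),
                        *,
                        baseline_window_days: int = BASELINE_WINDOW_DAYS,
                        baseline_grace_days: int = 0) -> TrajectoryClassification:
    """Classify one patient's full sampling trajectory.

    Clearance and response summaries use *on-treatment* samples (collection
    strictly after treatment start).  Baseline-undetected trajectories are
    flagged excluded from baseline-relative metrics but still receive
    clearance-free descriptive per-sample calls.
    """
    ok = sorted((s for s in samples if s.assay_status == "ok"),
                key=lambda s: s.collection_date)
    if not ok:
        raise ValueError("classify_trajectory needs at least one non-failed sample")
    pid = ok[0].patient_id
    baseline = derive_baseline(ok, treatment_start, baseline_window_days,
                               baseline_grace_days)
    baseline_detected = bool(baseline is not None and baseline.detected)

    traj = TrajectoryClassification(
        patient_id=pid,
        baseline=baseline,
        baseline_detected=baseline_detected,
        excluded_from_relative_metrics=not baseline_detected,
    )

    prior: PlasmaSample | None = None
    for s in ok:
        is_bl = baseline is not None and s.collection_date == baseline.collection_date
        traj.per_sample.append(call_sample(s, prior, baseline, config,
                                           is_baseline=is_bl))
        prior = s

    on_treatment = [c for c in traj.per_sample
                    if c.collection_date > treatment_start and not c.is_baseline]

    if baseline_detected:
        cleared_dates = [c.collection_date for c in on_treatment if c.cleared]
        traj.ever_cleared = bool(cleared_dates)
        traj.first_clearance_date = cleared_dates[0] if cleared_dates else None

        run = best_run = 0
        for c in on_treatment:
            run = run + 1 if c.cleared else 0
            best_run = max(best_run, run)
        traj.consecutive_clearance = best_run >= config.consecutive_clearance_n

        resp_dates = [c.collection_date for c in on_treatment
                      if c.cleared or bool(c.response_evaf_lt10)]
        traj.ever_response_lt10 = bool(resp_dates)
        traj.first_response_date = resp_dates[0] if resp_dates else None
        traj.last_response_date = resp_dates[-1] if resp_dates else None

        bl_evaf = baseline.evaf  # type: ignore[union-attr]
        traj.early_decrease = any(
            0 <= (c.collection_date - treatment_start).days
            <= config.early_decrease_window_days
            and _call_evaf(c) < bl_evaf
            for c in on_treatment)
        traj.early_rise = any(
            0 <= (c.collection_date - treatment_start).days
            <= config.early_rise_window_days
            and _call_evaf(c) > bl_evaf
            for c in on_treatment)
    return traj


def _call_evaf(call: SampleCall) -> float:
    return call.evaf if (call.detected and call.evaf is not None) else 0.0


def rule_prevalence(calls: Sequence[SampleCall], rule: str) -> tuple[int, int]:
    """(positives, evaluable) for a named rule over a set of sample calls.

    Calls where the rule is undefined (``None``) do not enter the
    denominator.  See :data:`ctdnamon.concordance.RULES` for rule names.
    """
    from .concordance import RULES  # local import to avoid a cycle
    extract = RULES[rule].extractor
    values = [extract(c) for c in calls]
    defined = [v for v in values if v is not None]
    return sum(bool(v) for v in defined), len(defined)
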