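"""Builders for small hand-made cohorts used across the test suite."""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd

from ctdnamon.cohort import Cohort, PlasmaSample

START = date(2021, 1, 1)


def day(d: int) -> date:
    return START + timedelta(days=d)


def sample(pid: str, d: int, evaf: float | None = None, *,
           failed: bool = False) -> PlasmaSample:
    """A typed plasma sample at day ``d`` relative to START."""
    if failed:
        return PlasmaSample(pid, day(d), assay_status="failed")
    return PlasmaSample(pid, day(d), detected=evaf is not None, evaf=evaf)


def sample_row(pid: str, d: int, evaf: float | None = None, *,
               failed: bool = False) -> dict:
    return {
        "patient_id": pid, "collection_date": day(d),
        "assay_status": "failed" if failed else "ok",
        "detected": False if failed else evaf is not None,
        "evaf": None if failed else evaf,
    }


def scan_row(pid: str, d: int, progression: bool = False, *,
             recist: str | None = None, target_mm: float | None = None,
             pseudo: bool = False) -> dict:
    return {
        "patient_id": pid, "scan_date": day(d),
        "radiologist_progression": progression,
        "recist_category": recist, "target_lesion_sum_mm": target_mm,
        "bone_pseudoprogression": pseudo,
    }


def patient_row(pid: str, *, start: date = START, end_day: int | None = None,
                failure: bool = False, death_day: int | None = None,
                followup_day: int = 720, measurable: bool = True,
                liver: bool = False, bone_only: bool = False) -> dict:
    sites = "liver;bone" if liver else ("bone" if bone_only else "lung;bone")
    return {
        "patient_id": pid, "menopausal_status": "post",
        "de_novo_metastatic": False, "disease_sites": sites,
        "bone_only": bone_only, "visceral": not bone_only,
        "therapy_line": 1, "cdk46i": "palbociclib", "et_partner": "AI",
        "treatment_start": start,
        "treatment_end": start + timedelta(days=end_day)
        if end_day is not None else None,
        "failure_event": failure,
        "death_date": start + timedelta(days=death_day)
        if death_day is not None else None,
        "last_followup": start + timedelta(days=followup_day),
        "measurable_disease": measurable,
        "endocrine_resistance": "none",
    }


def build_cohort(patients: list[dict], samples: list[dict],
                 scans: list[dict]) -> Cohort:
    pat = pd.DataFrame(patients)
    smp = pd.DataFrame(samples) if samples else pd.DataFrame(
        columns=["patient_id", "collection_date", "assay_status", "detected",
                 "evaf"])
    scn = pd.DataFrame(scans) if scans else pd.DataFrame(
        columns=["patient_id", "scan_date", "radiologist_progression",
                 "recist_category", "target_lesion_sum_mm",
                 "bone_pseudoprogression"])
    for df in (pat, smp, scn):
        for col in df.columns:
            if df[col].dtype == float:
                df[col] = df[col].astype(object).where(df[col].notna(), None)
    smp = smp.sort_values(["patient_id", "collection_date"]).reset_index(drop=True)
    scn = scn.sort_values(["patient_id", "scan_date"]).reset_index(drop=True)
    return Cohort(patients=pat.reset_index(drop=True), samples=smp, scans=scn)
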