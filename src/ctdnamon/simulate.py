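"""Synthetic longitudinal ctDNA cohorts with known ground truth.

Two generation modes share one configuration and one output shape (the three
cohort tables plus a per-patient truth table, regenerable bit-for-bit from
``(config, seed)``):

* **kinetic** — a single-compartment latent eVAF path per patient:
  exponential decline ``e0 * exp(-k t)`` until a resistance time ``t_res``,
  then exponential regrowth.  Baseline eVAF is log-normal (cohort median
  0.5%, multiplicatively higher with liver metastases); measurements carry
  multiplicative log-normal noise; detection is a sigmoid in log-eVAF
  anchored at 95% detection at the LoD95 (0.001%).  Radiographic progression
  occurs at the first scheduled scan after the latent burden regrows past
  ``failure_threshold`` × nadir (and past a floor fraction of baseline, so
  deep molecular responders regrow longer), and treatment failure follows
  shortly after; resistance times shorten with higher baseline eVAF, which
  builds in the prognostic direction of baseline ctDNA.  No claim of
  biological fidelity is made — this is the simplest kinetic model
  reproducing the qualitative structure the analyses assume.

* **hazard** — a piecewise-exponential failure model for clean
  parameter-recovery experiments: ctDNA clearance is assigned with a fixed
  probability at a visit-aligned time and multiplies the failure hazard by a
  configured hazard ratio from that time on.  With the ratio at 1 the
  clearance label is independent of outcome (type-I-error checks); with a
  strong ratio the time-varying Cox model should recover it.  Clearance
  times sit exactly on the sampling grid so the observed first cleared
  sample coincides with the latent switch time.

Blood draws follow the study-style schedule — baseline, day 15, day 28
(cycle 2), then every ~3 months, plus a draw at treatment failure — and
scans a baseline staging scan plus restaging every ~115 days (the cohort's
median 3.8-month interval).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .cohort import DAYS_PER_MONTH, Cohort

__all__ = ["SimulationConfig", "generate", "scenario", "detection_probability",
           "generate_variant_frame", "SCENARIOS"]

_ORIGIN = date(2020, 1, 1)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort generator.

    Rates are per month; eVAF values are on the percent scale; the seed
    fully determines the output.
    """

    n_patients: int = 50
    seed: int = 0
    mode: str = "kinetic"  # kinetic | hazard

    # baseline eVAF (percent, log-normal across patients)
    baseline_evaf_median: float = 0.5
    baseline_evaf_log_sd: float = 2.0
    liver_fraction: float = 0.35
    liver_evaf_multiplier: float = 2.92 / 0.32  # ratio of printed medians

    # kinetics
    decline_rate_median: float = 0.35
    decline_rate_log_sd: float = 1.0
    resistance_time_median_months: float = 13.0
    resistance_time_log_sd: float = 0.5
    resistance_evaf_exponent: float = 0.15  # higher baseline -> earlier resistance
    regrowth_rate_median: float = 0.35
    regrowth_rate_log_sd: float = 0.5

    # measurement & detection
    lod95: float = 0.001
    detection_slope_ln: float = 0.7
    measurement_noise_log_sd: float = 0.25
    assay_failure_rate: float = 0.03

    # schedules (days from treatment start)
    baseline_sample_day: int = -3
    sample_schedule_days: tuple[int, ...] = (15, 28)
    sample_interval_days: int = 91
    sampling_horizon_months: float = 18.0  # blood draws stop here (kinetic)
    first_scan_day: int = 88
    scan_interval_days: int = 115
    diameter_noise_log_sd: float = 0.2

    # outcome linkage (kinetic mode)
    failure_threshold: float = 1.2          # regrowth multiple of nadir
    progression_floor_fraction: float = 0.2  # of baseline eVAF
    failure_lag_days: int = 7
    followup_min_months: float = 18.0
    followup_max_months: float = 48.0
    death_mean_months_after_failure: float = 10.0
    pseudoprogression_rate: float = 3 / 234
    measurable_fraction: float = 0.63

    # hazard mode
    baseline_hazard_per_month: float = 0.05
    clearance_probability: float = 0.4
    clearance_hr: float = 1.0
    clearance_times_months: tuple[float, ...] = (0.5, 3.0, 6.0)
    censoring_time_months: float = 36.0

    def __post_init__(self) -> None:
        if self.mode not in {"kinetic", "hazard"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lod95 <= 0:
            raise ValueError("lod95 must be > 0")
        for name in ("decline_rate_median", "regrowth_rate_median",
                     "resistance_time_median_months", "baseline_hazard_per_month"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not all(b > a for a, b in zip(self.sample_schedule_days,
                                         self.sample_schedule_days[1:])):
            raise ValueError("sample_schedule_days must be strictly increasing")


def detection_probability(evaf: np.ndarray | float, lod95: float = 0.001,
                          slope_ln: float = 0.7) -> np.ndarray | float:
    """Sigmoidal assay detection curve, anchored at P=0.95 at the LoD95.

    Logistic in ln(eVAF); the anchor gives the half-detection point
    ``lod50 = lod95 * exp(-slope_ln * ln 19)``.  Monotone non-decreasing in
    eVAF by construction.
    """
    ln_lod50 = math.log(lod95) - slope_ln * math.log(19.0)
    with np.errstate(divide="ignore"):
        z = (np.log(evaf) - ln_lod50) / slope_ln
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


SCENARIOS = ("null_effect", "strong_clearance_benefit", "study_like")


def scenario(name: str, n_patients: int = 50, seed: int = 0,
             **overrides) -> SimulationConfig:
    """Named study conditions.

    ``study_like`` — kinetic defaults tuned so the cohort's summary outputs
    sit in the study's ballpark (median baseline eVAF, high baseline
    detection, ~30% clearance).  ``null_effect`` — hazard mode with the
    clearance label assigned at the first on-treatment visit and no effect
    on the failure hazard (type-I error checks).
    ``strong_clearance_benefit`` — hazard mode with the failure hazard
    multiplied by 0.07 after clearance (the scale of the reported
    time-varying estimate).
    """
    if name == "study_like":
        cfg = SimulationConfig(n_patients=n_patients, seed=seed, mode="kinetic")
    elif name == "null_effect":
        cfg = SimulationConfig(n_patients=n_patients, seed=seed, mode="hazard",
                               clearance_hr=1.0,
                               clearance_times_months=(0.5,))
    elif name == "strong_clearance_benefit":
        cfg = SimulationConfig(n_patients=n_patients, seed=seed, mode="hazard",
                               clearance_hr=0.07)
    else:
        raise ValueError(f"unknown scenario {name!r}; known: {SCENARIOS}")
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------

def _month_to_date(start: date, months: float) -> date:
    return start + timedelta(days=round(months * DAYS_PER_MONTH))


def _draw_sites(rng: np.random.Generator, liver: bool) -> tuple[str, bool, bool]:
    """(disease_sites, visceral, bone_only) with consistent flags."""
    sites = set()
    if liver:
        sites.add("liver")
    if rng.random() < 0.35:
        sites.add("lung")
    bone = rng.random() < 0.6
    if bone:
        sites.add("bone")
    if rng.random() < 0.3:
        sites.add("nodal")
    visceral = "liver" in sites or "lung" in sites
    bone_only = sites == {"bone"}
    if not sites:
        sites = {"bone"}
        bone_only = True
    return ";".join(sorted(sites)), visceral, bone_only


def _patient_row(rng: np.random.Generator, pid: str, start: date,
                 liver: bool, measurable: bool) -> dict:
    sites, visceral, bone_only = _draw_sites(rng, liver)
    return {
        "patient_id": pid,
        "menopausal_status": "pre" if rng.random() < 0.19 else "post",
        "de_novo_metastatic": bool(rng.random() < 0.26),
        "disease_sites": sites,
        "bone_only": bone_only,
        "visceral": visceral,
        "therapy_line": int(rng.choice([1, 2, 3], p=[0.79, 0.19, 0.02])),
        "cdk46i": str(rng.choice(["palbociclib", "ribociclib", "abemaciclib"],
                                 p=[0.79, 0.19, 0.02])),
        "et_partner": str(rng.choice(["AI", "SERD", "SERM"],
                                     p=[0.63, 0.35, 0.02])),
        "treatment_start": start,
        "measurable_disease": measurable,
        "endocrine_resistance": str(rng.choice(["none", "primary", "secondary"],
                                               p=[0.7, 0.15, 0.15])),
    }


def _sample_days(cfg: SimulationConfig, last_day: int) -> list[int]:
    days = [d for d in cfg.sample_schedule_days if d <= last_day]
    d = cfg.sample_interval_days
    while d <= last_day:
        days.append(d)
        d += cfg.sample_interval_days
    return days


def generate(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate (cohort tables, truth table); deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "kinetic":
        return _generate_kinetic(config, rng)
    return _generate_hazard(config, rng)


def _measured(rng: np.random.Generator, latent: float,
              cfg: SimulationConfig) -> tuple[bool, float | None]:
    """(detected, measured eVAF or None) for one draw of one latent value."""
    value = latent * math.exp(rng.normal(0.0, cfg.measurement_noise_log_sd))
    value = min(value, 99.0)
    p = float(detection_probability(value, cfg.lod95, cfg.detection_slope_ln))
    if rng.random() < p and value > 0:
        return True, round(value, 6)
    return False, None


def _generate_kinetic(cfg: SimulationConfig, rng: np.random.Generator
                      ) -> tuple[Cohort, pd.DataFrame]:
    patients, samples, scans, truth = [], [], [], []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        start = _ORIGIN + timedelta(days=int(rng.integers(0, 365)))
        liver = rng.random() < cfg.liver_fraction
        # keep the cohort geometric-median at the configured value: shift
        # liver up and non-liver down by complementary powers of the ratio
        mult = cfg.liver_evaf_multiplier
        med = cfg.baseline_evaf_median * (
            mult ** (1 - cfg.liver_fraction) if liver
            else mult ** (-cfg.liver_fraction))
        e0 = float(np.exp(rng.normal(math.log(med), cfg.baseline_evaf_log_sd)))
        e0 = min(e0, 40.0)
        k = float(np.exp(rng.normal(math.log(cfg.decline_rate_median),
                                    cfg.decline_rate_log_sd)))
        t_res_med = cfg.resistance_time_median_months * (
            (cfg.baseline_evaf_median / e0) ** cfg.resistance_evaf_exponent)
        t_res = float(np.exp(rng.normal(math.log(t_res_med),
                                        cfg.resistance_time_log_sd)))
        g = float(np.exp(rng.normal(math.log(cfg.regrowth_rate_median),
                                    cfg.regrowth_rate_log_sd)))
        measurable = rng.random() < cfg.measurable_fraction
        d0 = float(rng.uniform(15, 90)) if measurable else None

        def latent(t_months: float) -> float:
            if t_months <= t_res:
                return e0 * math.exp(-k * t_months)
            return e0 * math.exp(-k * t_res) * math.exp(g * (t_months - t_res))

        nadir = max(e0 * math.exp(-k * t_res), 1e-200)  # avoid underflow
        # latent radiographic progression: regrow past threshold x nadir and
        # past a floor fraction of baseline burden
        target = max(cfg.failure_threshold * nadir,
                     cfg.progression_floor_fraction * e0)
        t_prog = t_res + math.log(target / nadir) / g

        followup = float(rng.uniform(cfg.followup_min_months,
                                     cfg.followup_max_months))
        scan_days = list(range(cfg.first_scan_day,
                               int(followup * DAYS_PER_MONTH) + 1,
                               cfg.scan_interval_days))
        prog_day = None
        for d in scan_days:
            if d / DAYS_PER_MONTH >= t_prog:
                prog_day = d
                break
        failed = prog_day is not None
        failure_day = prog_day + cfg.failure_lag_days if failed else None
        end_day = failure_day if failed else int(followup * DAYS_PER_MONTH)

        death_day = None
        if failed:
            d_after = float(rng.exponential(cfg.death_mean_months_after_failure))
            cand = failure_day + int(d_after * DAYS_PER_MONTH)
            if cand <= int(followup * DAYS_PER_MONTH) + failure_day:
                death_day = cand
        last_day = death_day if death_day is not None else max(
            end_day, int(followup * DAYS_PER_MONTH))

        row = _patient_row(rng, pid, start, liver, measurable)
        row.update({
            "treatment_end": start + timedelta(days=failure_day) if failed else None,
            "failure_event": failed,
            "death_date": start + timedelta(days=death_day)
            if death_day is not None else None,
            "last_followup": start + timedelta(days=last_day),
        })
        patients.append(row)

        # plasma draws: baseline, early cycle, q3 months (up to the sampling
        # horizon), and a draw at treatment failure
        horizon_day = min(end_day,
                          int(cfg.sampling_horizon_months * DAYS_PER_MONTH))
        draw_days = [cfg.baseline_sample_day] + _sample_days(cfg, horizon_day)
        if failed and failure_day not in draw_days:
            draw_days.append(failure_day)
        first_cleared_truth = None
        for d in sorted(set(draw_days)):
            if rng.random() < cfg.assay_failure_rate:
                samples.append({"patient_id": pid,
                                "collection_date": start + timedelta(days=d),
                                "assay_status": "failed", "detected": False,
                                "evaf": None})
                continue
            lat = e0 if d <= 0 else latent(d / DAYS_PER_MONTH)
            detected, value = _measured(rng, lat, cfg)
            if d > 0 and not detected and first_cleared_truth is None:
                first_cleared_truth = d / DAYS_PER_MONTH
            samples.append({"patient_id": pid,
                            "collection_date": start + timedelta(days=d),
                            "assay_status": "ok", "detected": detected,
                            "evaf": value})

        # baseline staging scan on day 0, restaging per schedule
        scans.append({"patient_id": pid, "scan_date": start,
                      "radiologist_progression": False,
                      "recist_category": None if measurable else "non_measurable",
                      "target_lesion_sum_mm": round(d0, 1) if measurable else None,
                      "bone_pseudoprogression": False})
        pseudo_done = False
        for j, d in enumerate(scan_days):
            if d > end_day:
                break
            lat = latent(d / DAYS_PER_MONTH)
            is_prog = d == prog_day
            pseudo = (not is_prog and j == 0 and not pseudo_done
                      and rng.random() < cfg.pseudoprogression_rate * len(scan_days))
            pseudo_done = pseudo_done or pseudo
            if measurable:
                dnoise = math.exp(rng.normal(0.0, cfg.diameter_noise_log_sd))
                dsum = max(5.0, d0 * (max(lat, 1e-9) / e0) ** (1.0 / 3.0) * dnoise)
                if is_prog:
                    cat = "PD"
                elif lat <= 0.343 * e0:   # diameter at or below 70% of baseline
                    cat = "PR"
                else:
                    cat = "SD"
            else:
                dsum, cat = None, "non_measurable"
            scans.append({
                "patient_id": pid, "scan_date": start + timedelta(days=d),
                "radiologist_progression": bool(is_prog or pseudo),
                "recist_category": "PD" if (is_prog and not measurable) else cat,
                "target_lesion_sum_mm": round(dsum, 1) if dsum else None,
                "bone_pseudoprogression": pseudo,
            })

        truth.append({
            "patient_id": pid, "liver": liver, "baseline_evaf": e0,
            "decline_rate": k, "resistance_time_months": t_res,
            "regrowth_rate": g, "progression_time_months": t_prog,
            "failure_months": failure_day / DAYS_PER_MONTH if failed else None,
            "event": failed,
            "followup_months": last_day / DAYS_PER_MONTH,
            "first_cleared_months": first_cleared_truth,
            "measurable": measurable,
        })
    return _assemble(patients, samples, scans), pd.DataFrame(truth)


def _generate_hazard(cfg: SimulationConfig, rng: np.random.Generator
                     ) -> tuple[Cohort, pd.DataFrame]:
    patients, samples, scans, truth = [], [], [], []
    h0 = cfg.baseline_hazard_per_month
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        start = _ORIGIN + timedelta(days=int(rng.integers(0, 365)))
        liver = rng.random() < cfg.liver_fraction
        e0 = float(np.exp(rng.normal(math.log(cfg.baseline_evaf_median),
                                     cfg.baseline_evaf_log_sd)))
        e0 = float(min(max(e0, 0.01), 40.0))

        assigned = rng.random() < cfg.clearance_probability
        t_clear = float(rng.choice(cfg.clearance_times_months)) if assigned else None

        u = float(rng.exponential(1.0))  # unit-exponential inverse transform
        if t_clear is None or u < h0 * t_clear:
            t_fail = u / h0
        else:
            t_fail = t_clear + (u - h0 * t_clear) / (h0 * cfg.clearance_hr)
        censor = cfg.censoring_time_months
        event = t_fail <= censor
        duration = min(t_fail, censor)
        observed_clear = (t_clear is not None and t_clear < duration)

        end_date = _month_to_date(start, duration)
        death_date = None
        if event:
            d_after = float(rng.exponential(cfg.death_mean_months_after_failure))
            if duration + d_after <= censor + 12:
                death_date = _month_to_date(start, duration + d_after)
        last = death_date if death_date is not None else _month_to_date(
            start, max(duration, censor))

        row = _patient_row(rng, pid, start, liver, measurable=True)
        row.update({
            "treatment_end": end_date if event else None,
            "failure_event": bool(event),
            "death_date": death_date,
            "last_followup": last,
        })
        patients.append(row)

        visit_months = [0.5] + [3.0 * j for j in range(1, int(censor / 3) + 1)]
        visit_months = [m for m in visit_months if m < duration]
        samples.append({"patient_id": pid,
                        "collection_date": start + timedelta(
                            days=cfg.baseline_sample_day),
                        "assay_status": "ok", "detected": True,
                        "evaf": round(e0, 6)})
        seen_dates = {start + timedelta(days=cfg.baseline_sample_day)}
        for m in visit_months + ([duration] if event else []):
            when = _month_to_date(start, m)
            if when in seen_dates:
                continue
            seen_dates.add(when)
            cleared = observed_clear and m >= t_clear
            noise = math.exp(rng.normal(0.0, cfg.measurement_noise_log_sd))
            samples.append({
                "patient_id": pid,
                "collection_date": when,
                "assay_status": "ok",
                "detected": not cleared,
                "evaf": None if cleared else round(e0 * noise, 6)})

        scans.append({"patient_id": pid, "scan_date": start,
                      "radiologist_progression": False, "recist_category": None,
                      "target_lesion_sum_mm": None,
                      "bone_pseudoprogression": False})
        if event:
            scans.append({"patient_id": pid,
                          "scan_date": _month_to_date(start, duration),
                          "radiologist_progression": True,
                          "recist_category": "PD", "target_lesion_sum_mm": None,
                          "bone_pseudoprogression": False})

        truth.append({
            "patient_id": pid, "liver": liver, "baseline_evaf": e0,
            "assigned_clearance": assigned,
            "clearance_time_months": t_clear if observed_clear else None,
            "failure_months": t_fail if event else None,
            "event": bool(event), "duration_months": duration,
        })
    return _assemble(patients, samples, scans), pd.DataFrame(truth)


def _assemble(patients: list[dict], samples: list[dict], scans: list[dict]
              ) -> Cohort:
    pat = pd.DataFrame(patients).sort_values("patient_id").reset_index(drop=True)
    smp = pd.DataFrame(samples).sort_values(
        ["patient_id", "collection_date"]).reset_index(drop=True)
    scn = pd.DataFrame(scans).sort_values(
        ["patient_id", "scan_date"]).reset_index(drop=True)
    # object dtype with None (not NaN) matches the reader's output shape
    for df in (pat, smp, scn):
        for col in df.columns:
            if df[col].dtype == float:
                df[col] = df[col].astype(object).where(df[col].notna(), None)
    return Cohort(patients=pat, samples=smp, scans=scn)


# ---------------------------------------------------------------------------
# synthetic variant tables (for the WES filter / panel-design module)

_CONSEQUENCES = ("Missense_Mutation", "Nonsense_Mutation", "Silent",
                 "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site",
                 "3'UTR", "Intron", "In_Frame_Del", "In_Frame_Ins")


def generate_variant_frame(rng: np.random.Generator, n_variants: int,
                           patient_id: str = "P001") -> pd.DataFrame:
    """A random MAF-like variant table spanning all filter branches."""
    genes = [f"GENE{int(g)}" for g in rng.integers(1, 500, n_variants)]
    df = pd.DataFrame({
        "patient_id": patient_id,
        "gene": genes,
        "chrom": [f"chr{int(c)}" for c in rng.integers(1, 23, n_variants)],
        "pos": rng.integers(1, 2_000_000, n_variants),
        "ref": rng.choice(list("ACGT"), n_variants),
        "alt": rng.choice(list("ACGT"), n_variants),
        "depth": rng.integers(20, 600, n_variants),
        "vaf": np.round(rng.uniform(0.0, 1.0, n_variants), 4),
        "consequence": rng.choice(_CONSEQUENCES, n_variants),
        "population_af": np.round(
            np.where(rng.random(n_variants) < 0.2,
                     rng.uniform(0, 0.05, n_variants), 0.0), 5),
        "germline_flag": rng.random(n_variants) < 0.05,
        "chip_flag": rng.random(n_variants) < 0.05,
    })
    return df
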