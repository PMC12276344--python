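"""Longitudinal cohort data model: schemas, readers/writers, validation.

A cohort is three tables (delimited text, CSV or TSV by extension):

* ``patients`` — one row per patient: demographics, disease sites, therapy,
  treatment start/stop, failure/death dates and flags.
* ``plasma_samples`` — one row per blood draw: assay status, ctDNA detected
  flag, and the estimated variant allele fraction (eVAF) on the *percent*
  scale (0.5 means 0.5%).  Undetected or failed samples carry no eVAF —
  "not detected" is kept distinct from "detected at a tiny eVAF".
* ``imaging`` — one row per restaging scan: the radiologist's progression
  adjudication, the RECIST v1.1 category, the target-lesion diameter sum for
  measurable disease, and a bone-pseudoprogression flag.

Dates are ISO-8601 calendar dates; durations in months use a fixed
days-per-month convention (:data:`DAYS_PER_MONTH`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed calendar convention for converting day counts to months.
DAYS_PER_MONTH = 30.4375

#: Default baseline blood-draw window: latest non-failed sample drawn within
#: this many days *before* treatment start (grace days after start default 0).
BASELINE_WINDOW_DAYS = 42

DISEASE_SITES = frozenset({"liver", "lung", "bone", "nodal", "other"})
MENOPAUSAL = frozenset({"pre", "post"})
CDK46I = frozenset({"palbociclib", "ribociclib", "abemaciclib"})
ET_PARTNERS = frozenset({"AI", "SERD", "SERM"})
ENDOCRINE_RESISTANCE = frozenset({"none", "primary", "secondary"})
ASSAY_STATUS = frozenset({"ok", "failed"})
RECIST_CATEGORIES = frozenset({"CR", "PR", "SD", "PD", "non_measurable"})

PATIENT_COLUMNS = [
    "patient_id", "menopausal_status", "de_novo_metastatic", "disease_sites",
    "bone_only", "visceral", "therapy_line", "cdk46i", "et_partner",
    "treatment_start", "treatment_end", "failure_event", "death_date",
    "last_followup", "measurable_disease", "endocrine_resistance",
]
SAMPLE_COLUMNS = ["patient_id", "collection_date", "assay_status", "detected", "evaf"]
SCAN_COLUMNS = [
    "patient_id", "scan_date", "radiologist_progression", "recist_category",
    "target_lesion_sum_mm", "bone_pseudoprogression",
]

_DATE_COLS = {
    "patients": ["treatment_start", "treatment_end", "death_date", "last_followup"],
    "plasma_samples": ["collection_date"],
    "imaging": ["scan_date"],
}
_BOOL_COLS = {
    "patients": ["de_novo_metastatic", "bone_only", "visceral", "failure_event",
                 "measurable_disease"],
    "plasma_samples": ["detected"],
    "imaging": ["radiologist_progression", "bone_pseudoprogression"],
}
_KEY_COLS = {
    "patients": ["patient_id"],
    "plasma_samples": ["patient_id", "collection_date"],
    "imaging": ["patient_id", "scan_date"],
}


class CohortError(ValueError):
    """Base error for malformed cohort inputs."""


class SchemaError(CohortError):
    """A column is missing or a value cannot be parsed to its declared type."""


class ReferentialError(CohortError):
    """A sample or scan references a patient_id absent from the patients table."""


@dataclass(frozen=True)
class PlasmaSample:
    """One plasma assay result.

    ``evaf`` is on the percent scale and present iff the assay succeeded and
    ctDNA was detected.
    """

    patient_id: str
    collection_date: date
    assay_status: str = "ok"
    detected: bool = False
    evaf: float | None = None
    is_baseline: bool = False

    def __post_init__(self) -> None:
        if self.assay_status not in ASSAY_STATUS:
            raise SchemaError(f"bad assay_status {self.assay_status!r}")
        if self.assay_status == "failed" and (self.detected or self.evaf is not None):
            raise SchemaError("failed samples carry neither detected nor evaf")
        if self.detected != (self.evaf is not None) and self.assay_status == "ok":
            raise SchemaError("evaf must be present iff detected (assay ok)")
        if self.evaf is not None and not self.evaf > 0:
            raise SchemaError("evaf must be > 0 when present")


@dataclass(frozen=True)
class ImagingAssessment:
    """One restaging scan with radiologist and RECIST adjudications."""

    patient_id: str
    scan_date: date
    radiologist_progression: bool = False
    recist_category: str | None = None
    target_lesion_sum_mm: float | None = None
    bone_pseudoprogression: bool = False


@dataclass(frozen=True)
class AssayConfig:
    """Tumor-informed assay parameters.

    lod95
        eVAF (percent) at which ctDNA is detected in 95% of replicates.
    min_panel_variants
        minimum validated somatic variants required for a usable panel.
    max_panel_targets
        maximum primer-pair targets on a personalized panel.
    """

    lod95: float = 0.001
    min_panel_variants: int = 8
    max_panel_targets: int = 48

    def __post_init__(self) -> None:
        if not 0 < self.lod95 < 100:
            raise ValueError("lod95 must be in (0, 100) percent")
        if self.min_panel_variants > self.max_panel_targets:
            raise ValueError("min_panel_variants must be <= max_panel_targets")


@dataclass
class Cohort:
    """A validated longitudinal cohort: patients, plasma samples, scans."""

    patients: pd.DataFrame
    samples: pd.DataFrame
    scans: pd.DataFrame

    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    def samples_for(self, patient_id: str) -> pd.DataFrame:
        return self.samples[self.samples["patient_id"] == patient_id]

    def scans_for(self, patient_id: str) -> pd.DataFrame:
        return self.scans[self.scans["patient_id"] == patient_id]

    def patient_row(self, patient_id: str) -> pd.Series:
        sub = self.patients[self.patients["patient_id"] == patient_id]
        if sub.empty:
            raise KeyError(patient_id)
        return sub.iloc[0]


@dataclass(frozen=True)
class ValidationIssue:
    level: str  # "warning" | "error"
    code: str
    message: str


def months_between(later: date, earlier: date) -> float:
    """Signed interval in months under the fixed day convention."""
    return (later - earlier).days / DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# parsing helpers

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def _parse_dates(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    for col in cols:
        if col not in df.columns:
            continue
        try:
            parsed = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{table}.{col}: unparseable date ({exc})") from exc
        df[col] = [None if pd.isna(v) else v.date() for v in parsed]


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bools(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    for col in cols:
        if col not in df.columns:
            continue
        def conv(v: object) -> bool:
            if isinstance(v, bool):
                return v
            s = str(v).strip().lower()
            if s in _TRUE:
                return True
            if s in _FALSE or s == "nan":
                return False
            raise SchemaError(f"{table}.{col}: unparseable flag {v!r}")
        df[col] = df[col].map(conv)


def _check_enum(df: pd.DataFrame, col: str, allowed: frozenset, table: str,
                optional: bool = False) -> None:
    if col not in df.columns:
        return
    for v in df[col]:
        if pd.isna(v) or v in ("", None):
            if optional:
                continue
            raise SchemaError(f"{table}.{col}: missing required value")
        if str(v) not in allowed:
            raise SchemaError(f"{table}.{col}: {v!r} not in {sorted(allowed)}")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing columns {missing}")


def _drop_duplicates(df: pd.DataFrame, keys: Sequence[str], table: str) -> pd.DataFrame:
    dup = df.duplicated(subset=keys, keep="first")
    if dup.any():
        logger.warning("%s: %d duplicate row(s) on %s dropped (keep-first)",
                       table, int(dup.sum()), keys)
    return df[~dup].reset_index(drop=True)


def _read_table(path: Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in df.columns:  # empty cells are typed None, never NaN
        df[col] = [None if v == "" else v for v in df[col]]
    required = {"patients": PATIENT_COLUMNS[:1] + PATIENT_COLUMNS[9:10],
                "plasma_samples": SAMPLE_COLUMNS[:4],
                "imaging": SCAN_COLUMNS[:3]}[table]
    _require_columns(df, required, table)
    _parse_dates(df, _DATE_COLS[table], table)
    _parse_bools(df, _BOOL_COLS[table], table)
    return df


def read_cohort(cohort_dir: str | Path, *,
                patients: str = "patients",
                samples: str = "plasma_samples",
                scans: str = "imaging") -> Cohort:
    """Read, parse, cross-reference and sort a cohort from a directory.

    CSV or TSV is chosen by extension; each logical table may exist with
    either extension.  Duplicate keyed rows are dropped keep-first with a
    logged warning; unknown patient ids in samples/scans raise
    :class:`ReferentialError`.
    """
    cohort_dir = Path(cohort_dir)

    def find(stem: str) -> Path:
        for ext in (".csv", ".tsv"):
            p = cohort_dir / f"{stem}{ext}"
            if p.exists():
                return p
        raise FileNotFoundError(f"no {stem}.csv or {stem}.tsv in {cohort_dir}")

    pat = _read_table(find(patients), "patients")
    smp = _read_table(find(samples), "plasma_samples")
    scn = _read_table(find(scans), "imaging")

    for col in ("therapy_line",):
        if col in pat.columns:
            pat[col] = pat[col].map(lambda v: int(v) if v not in (None, "") else None)
    _check_enum(pat, "menopausal_status", MENOPAUSAL, "patients", optional=True)
    _check_enum(pat, "cdk46i", CDK46I, "patients", optional=True)
    _check_enum(pat, "et_partner", ET_PARTNERS, "patients", optional=True)
    _check_enum(pat, "endocrine_resistance", ENDOCRINE_RESISTANCE, "patients",
                optional=True)
    if "disease_sites" in pat.columns:
        def parse_sites(v: object) -> str:
            if v in (None, ""):
                return ""
            sites = [s for s in str(v).split(";") if s]
            bad = [s for s in sites if s not in DISEASE_SITES]
            if bad:
                raise SchemaError(f"patients.disease_sites: unknown site(s) {bad}")
            return ";".join(sites)
        pat["disease_sites"] = pat["disease_sites"].map(parse_sites)

    _check_enum(smp, "assay_status", ASSAY_STATUS, "plasma_samples")
    if "evaf" in smp.columns:
        smp["evaf"] = pd.Series(
            [float(v) if v not in (None, "") else None for v in smp["evaf"]],
            index=smp.index, dtype=object)
    else:
        smp["evaf"] = None
    _check_enum(scn, "recist_category", RECIST_CATEGORIES, "imaging", optional=True)
    if "target_lesion_sum_mm" in scn.columns:
        scn["target_lesion_sum_mm"] = pd.Series(
            [float(v) if v not in (None, "") else None
             for v in scn["target_lesion_sum_mm"]],
            index=scn.index, dtype=object)
    else:
        scn["target_lesion_sum_mm"] = None

    pat = _drop_duplicates(pat, _KEY_COLS["patients"], "patients")
    smp = _drop_duplicates(smp, _KEY_COLS["plasma_samples"], "plasma_samples")
    scn = _drop_duplicates(scn, _KEY_COLS["imaging"], "imaging")

    known = set(pat["patient_id"])
    for table, df, col in (("plasma_samples", smp, "collection_date"),
                           ("imaging", scn, "scan_date")):
        for i, row in df.iterrows():
            if row["patient_id"] not in known:
                raise ReferentialError(
                    f"{table} row {i} ({row['patient_id']!r}, {row[col]}): "
                    "patient_id not in patients table")

    pat = pat.sort_values(["patient_id"]).reset_index(drop=True)
    smp = smp.sort_values(["patient_id", "collection_date"]).reset_index(drop=True)
    scn = scn.sort_values(["patient_id", "scan_date"]).reset_index(drop=True)
    return Cohort(patients=pat, samples=smp, scans=scn)


def write_cohort(cohort: Cohort, out_dir: str | Path, *, sep: str = ",") -> None:
    """Write the three cohort tables; inverse of :func:`read_cohort`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".tsv" if sep == "\t" else ".csv"
    for name, df in (("patients", cohort.patients),
                     ("plasma_samples", cohort.samples),
                     ("imaging", cohort.scans)):
        out = df.copy()
        for col in out.columns:
            out[col] = out[col].map(lambda v: "" if v is None or (
                isinstance(v, float) and pd.isna(v)) else v)
        out.to_csv(out_dir / f"{name}{ext}", sep=sep, index=False)


# ---------------------------------------------------------------------------
# baseline derivation

def samples_from_frame(df: pd.DataFrame) -> list[PlasmaSample]:
    """Convert sample rows (one patient or many) into typed records."""
    out = []
    for _, r in df.iterrows():
        failed = r["assay_status"] == "failed"
        out.append(PlasmaSample(
            patient_id=r["patient_id"],
            collection_date=r["collection_date"],
            assay_status=r["assay_status"],
            detected=False if failed else bool(r["detected"]),
            evaf=None if failed else (r["evaf"] if bool(r["detected"]) else None),
        ))
    return out


def derive_baseline(samples: Sequence[PlasmaSample], treatment_start: date,
                    window_days: int = BASELINE_WINDOW_DAYS,
                    grace_days: int = 0) -> PlasmaSample | None:
    """Pick the baseline draw: latest non-failed sample in the window.

    The window is ``[treatment_start - window_days, treatment_start +
    grace_days]``.  Returns ``None`` when no eligible sample exists (the
    caller decides whether that excludes the patient).  Idempotent and
    independent of input order.
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    eligible = [s for s in samples
                if s.assay_status == "ok"
                and (treatment_start - s.collection_date).days <= window_days
                and (s.collection_date - treatment_start).days <= grace_days]
    if not eligible:
        return None
    best = max(eligible, key=lambda s: s.collection_date)
    return replace(best, is_baseline=True)


# ---------------------------------------------------------------------------
# validation

def validate_cohort(cohort: Cohort, *,
                    baseline_window_days: int = BASELINE_WINDOW_DAYS,
                    baseline_grace_days: int = 0) -> list[ValidationIssue]:
    """Report-only consistency checks; never mutates the cohort.

    Errors flag invariant breaches (impossible date orderings, contradictory
    flags); warnings flag analyzability problems (no baseline-window sample,
    fewer than two samples, scans predating treatment).
    """
    issues: list[ValidationIssue] = []

    def err(code: str, msg: str) -> None:
        issues.append(ValidationIssue("error", code, msg))

    def warn(code: str, msg: str) -> None:
        issues.append(ValidationIssue("warning", code, msg))

    for _, p in cohort.patients.iterrows():
        pid = p["patient_id"]
        start = p["treatment_start"]
        if p.get("treatment_end") is not None and p["treatment_end"] < start:
            err("treatment_end_before_start", f"{pid}: treatment_end < treatment_start")
        if p.get("last_followup") is not None and p["last_followup"] < start:
            err("followup_before_start", f"{pid}: last_followup < treatment_start")
        if p.get("death_date") is not None and p["death_date"] < start:
            err("death_before_start", f"{pid}: death_date < treatment_start")
        if bool(p.get("visceral")) and bool(p.get("bone_only")):
            err("visceral_and_bone_only", f"{pid}: visceral and bone_only both set")

        psamples = samples_from_frame(cohort.samples_for(pid))
        if len(psamples) < 2:
            warn("too_few_samples", f"{pid}: fewer than 2 plasma samples")
        baseline = derive_baseline(psamples, start, baseline_window_days,
                                   baseline_grace_days)
        if baseline is None:
            warn("no_baseline_sample", f"{pid}: no non-failed sample in the "
                 f"baseline window")
        elif not baseline.detected:
            warn("baseline_undetected", f"{pid}: baseline sample has no ctDNA "
                 "detected; excluded from baseline-relative metrics")

        for _, sc in cohort.scans_for(pid).iterrows():
            if sc["scan_date"] < start:
                warn("scan_before_treatment", f"{pid}: scan {sc['scan_date']} "
                     "precedes treatment start")

    for _, s in cohort.samples.iterrows():
        failed = s["assay_status"] == "failed"
        if failed and (bool(s["detected"]) or s["evaf"] is not None):
            err("failed_sample_with_result",
                f"{s['patient_id']} {s['collection_date']}: failed sample "
                "carries a detected flag or eVAF")
        elif not failed:
            has_evaf = s["evaf"] is not None
            if bool(s["detected"]) != has_evaf:
                err("evaf_detected_mismatch",
                    f"{s['patient_id']} {s['collection_date']}: evaf present "
                    "iff detected is violated")
            if has_evaf and not s["evaf"] > 0:
                err("nonpositive_evaf",
                    f"{s['patient_id']} {s['collection_date']}: evaf <= 0")
    return issues
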