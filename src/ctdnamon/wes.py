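"""Somatic variant filtering, TMB, driver annotation, and panel design.

Variants from tumor-only exome calling are filtered with fixed criteria:
minimum depth 100; tumor VAF above 5% (sequencing-error floor); VAF inside
40–60% or above 90% removed as presumed germline; a protein-altering
consequence whitelist; population allele frequency below 1%; and removal of
variants flagged germline or CHIP by the buffy-coat control.  Each removed
variant carries exactly one reason code — the first failing rule in a fixed
order — so filter reports are deterministic.

Tumor mutational burden is kept variants per megabase of captured territory
(capture size is a configuration parameter).  Personalized panel design
ranks kept variants by descending tumor VAF (genomic-coordinate tie-break),
takes up to ``max_panel_targets`` targets, and succeeds only when at least
``min_panel_variants`` variants survive QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .cohort import AssayConfig

__all__ = [
    "VariantRecord", "FilterConfig", "FilterResult", "PanelDesign",
    "filter_somatic", "compute_tmb", "design_panel", "read_maf",
    "read_driver_genes", "REASON_ORDER", "CONSEQUENCE_WHITELIST",
]

CONSEQUENCE_WHITELIST = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Ins",
    "Frame_Shift_Del", "Splice_Site", "In_Frame_Ins", "In_Frame_Del",
})

#: First-failing reason-code order (fixed so reports are deterministic).
REASON_ORDER = ("low_depth", "low_vaf", "germline_band", "high_vaf_germline",
                "consequence", "population_af", "buffy_coat", "chip")


@dataclass(frozen=True)
class VariantRecord:
    """One somatic variant call (1-based coordinates, VAF as a fraction)."""

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    vaf: float
    consequence: str
    population_af: float | None = None
    germline_flag: bool = False
    chip_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.vaf <= 1:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.population_af is not None and not 0 <= self.population_af <= 1:
            raise ValueError("population_af outside [0, 1]")

    @property
    def coordinate(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterConfig:
    """Somatic-filter thresholds (defaults match the fixed criteria)."""

    min_depth: int = 100
    min_vaf: float = 0.05            # keep vaf strictly above this
    germline_band: tuple[float, float] = (0.40, 0.60)  # inclusive removal band
    high_vaf_cutoff: float = 0.90    # remove vaf strictly above
    max_population_af: float = 0.01  # keep strictly below
    consequences: frozenset[str] = CONSEQUENCE_WHITELIST
    capture_size_mb: float = 35.0    # standard exome capture


@dataclass
class FilterResult:
    kept: list[VariantRecord]
    removed: list[tuple[VariantRecord, str]]
    tmb: float
    n_driver: int


@dataclass(frozen=True)
class PanelDesign:
    patient_id: str
    targets: tuple[VariantRecord, ...]
    success: bool
    failure_reason: str | None = None  # too_few_variants | wes_failed


def failing_reason(v: VariantRecord, config: FilterConfig = FilterConfig()
                   ) -> str | None:
    """First failing rule for one variant, or None if it passes all rules."""
    lo, hi = config.germline_band
    if v.depth < config.min_depth:
        return "low_depth"
    if v.vaf <= config.min_vaf:
        return "low_vaf"
    if lo <= v.vaf <= hi:
        return "germline_band"
    if v.vaf > config.high_vaf_cutoff:
        return "high_vaf_germline"
    if v.consequence not in config.consequences:
        return "consequence"
    if v.population_af is not None and v.population_af >= config.max_population_af:
        return "population_af"
    if v.germline_flag:
        return "buffy_coat"
    if v.chip_flag:
        return "chip"
    return None


def filter_somatic(variants: Sequence[VariantRecord],
                   driver_genes: set[str] | frozenset[str] = frozenset(),
                   config: FilterConfig = FilterConfig()) -> FilterResult:
    """Apply the somatic filter; order-independent in the kept/removed sets."""
    kept, removed = [], []
    for v in variants:
        reason = failing_reason(v, config)
        if reason is None:
            kept.append(v)
        else:
            removed.append((v, reason))
    tmb = compute_tmb(kept, config.capture_size_mb)
    n_driver = sum(v.gene in driver_genes for v in kept)
    return FilterResult(kept=kept, removed=removed, tmb=tmb, n_driver=n_driver)


def compute_tmb(kept: Sequence[VariantRecord], capture_size_mb: float) -> float:
    """Mutations per megabase over the captured territory."""
    if capture_size_mb <= 0:
        raise ValueError("capture_size_mb must be > 0")
    return len(kept) / capture_size_mb


def default_ranking(v: VariantRecord) -> tuple:
    return (-v.vaf, v.chrom, v.pos, v.ref, v.alt)


def design_panel(kept: Sequence[VariantRecord],
                 config: AssayConfig = AssayConfig(),
                 ranking: Callable[[VariantRecord], tuple] = default_ranking,
                 ) -> PanelDesign:
    """Select panel targets: top-ranked variants up to the target cap.

    Success requires at least ``min_panel_variants`` kept variants;
    otherwise the design fails with reason ``too_few_variants`` (mirroring
    attrition where too few target variants remain after panel QC).
    """
    pid = kept[0].patient_id if kept else ""
    ranked = sorted(kept, key=ranking)
    targets = tuple(ranked[:config.max_panel_targets])
    success = len(kept) >= config.min_panel_variants
    return PanelDesign(
        patient_id=pid, targets=targets, success=success,
        failure_reason=None if success else "too_few_variants",
    )


# ---------------------------------------------------------------------------
# readers

_MAF_ALIASES = {
    "Hugo_Symbol": "gene",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "t_depth": "depth",
    "Variant_Classification": "consequence",
    "Tumor_Sample_Barcode": "patient_id",
}


def read_maf(path: str | Path, patient_id: str | None = None
             ) -> list[VariantRecord]:
    """Read a MAF-like tab-delimited variant table.

    Accepts either the native field names (gene, chrom, pos, ref, alt,
    depth, vaf, consequence, population_af, germline_flag, chip_flag) or
    standard MAF columns (Hugo_Symbol, t_depth, t_alt_count → vaf, ...).
    Lines starting with ``#`` are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    df = df.rename(columns={k: v for k, v in _MAF_ALIASES.items()
                            if k in df.columns})
    if "vaf" not in df.columns and {"t_alt_count", "depth"} <= set(df.columns):
        df["vaf"] = df["t_alt_count"].astype(float) / df["depth"].astype(float)
    required = {"gene", "chrom", "pos", "ref", "alt", "depth", "vaf",
                "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"MAF missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(VariantRecord(
            patient_id=patient_id or r.get("patient_id", ""),
            gene=r["gene"], chrom=str(r["chrom"]), pos=int(r["pos"]),
            ref=r["ref"], alt=r["alt"], depth=int(float(r["depth"])),
            vaf=float(r["vaf"]), consequence=r["consequence"],
            population_af=float(r["population_af"])
            if r.get("population_af") not in (None, "",) else None,
            germline_flag=str(r.get("germline_flag", "")).lower()
            in {"true", "1", "yes"},
            chip_flag=str(r.get("chip_flag", "")).lower()
            in {"true", "1", "yes"},
        ))
    return out


def read_driver_genes(path: str | Path) -> frozenset[str]:
    """One gene symbol per line (stand-in for a cancer gene census list)."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh
                         if line.strip() and not line.startswith("#"))
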