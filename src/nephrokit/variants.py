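"""Somatic-variant hard filtering.

Candidate calls (already produced by an upstream caller) are graded against
the study's rule set. A *somatic*-grade call must have: no evidence in the
matched normal (any alt-supporting read or a non-reference normal genotype
fails), no dbSNP overlap, tumour base coverage >= 10x (>= 20x when no
matched normal is available), VAF >= 0.1, phred-scaled site quality >= 100
for substitutions and >= 250 for indels, mapping quality >= 60 for indels,
autosomal location only, and — for indels — no control-called variant within
100 bp. All rules are evaluated (failures accumulate, no short-circuit).

*Signature*-grade substitutions additionally require genotype quality >= 10
in the normal and >= 99 in the tumour; samples without matched normals are
excluded from signature analysis entirely.

The driver report keeps non-synonymous classes (missense, start loss, stop
gain, in-frame insertion/deletion, frameshift) — in all genes when a matched
normal exists, restricted to a supplied driver-gene list otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .config import VariantConfig
from .errors import ConfigurationError, ValidationError

AUTOSOMES = {str(i) for i in range(1, 23)}

SOMATIC_RULES = (
    "normal_evidence",
    "dbsnp",
    "depth",
    "vaf",
    "site_qual",
    "mq",
    "autosome",
    "indel_proximity",
)


def normalize_chrom(chrom: str) -> str:
    return str(chrom).removeprefix("chr").removeprefix("CHR")


@dataclass
class VariantRecord:
    """One candidate somatic call (one ALT allele)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    tumour_depth: int
    tumour_vaf: float
    site_qual: float
    mq: float
    tumour_gq: float | None = None
    normal_depth: int | None = None
    normal_alt_reads: int | None = None
    normal_gq: float | None = None
    normal_nonref_gt: bool | None = None
    dbsnp: bool = False
    gene: str | None = None
    annotation_class: str | None = None
    sample: str | None = None

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1 (got {self.pos})")
        if not 0.0 <= self.tumour_vaf <= 1.0:
            raise ValidationError(f"VAF must be in [0,1] (got {self.tumour_vaf})")

    @property
    def vtype(self) -> str:
        return "snv" if len(self.ref) == len(self.alt) == 1 else "indel"

    @property
    def has_normal(self) -> bool:
        return self.normal_depth is not None


@dataclass
class FilterVerdict:
    """Per-record verdict: pass flag and the rules it failed."""

    passed: bool
    reasons: list[str]
    grade: str = "somatic"


def _somatic_reasons(
    rec: VariantRecord,
    matched_normal: bool,
    cfg: VariantConfig,
    control_index: dict[str, list[int]],
) -> list[str]:
    reasons = []
    if matched_normal:
        evidence = (rec.normal_alt_reads or 0) >= cfg.normal_evidence_min_reads or bool(rec.normal_nonref_gt)
        if evidence:
            reasons.append("normal_evidence")
    if rec.dbsnp:
        reasons.append("dbsnp")
    min_depth = cfg.min_depth if matched_normal else cfg.min_depth_no_normal
    if rec.tumour_depth < min_depth:
        reasons.append("depth")
    if rec.tumour_vaf < cfg.min_vaf:
        reasons.append("vaf")
    min_qual = cfg.min_qual_snv if rec.vtype == "snv" else cfg.min_qual_indel
    if rec.site_qual < min_qual:
        reasons.append("site_qual")
    if rec.vtype == "indel" and rec.mq < cfg.min_mq_indel:
        reasons.append("mq")
    if rec.chrom not in AUTOSOMES:
        reasons.append("autosome")
    if rec.vtype == "indel":
        near = control_index.get(rec.chrom, [])
        if any(abs(rec.pos - p) <= cfg.indel_proximity_bp for p in near):
            reasons.append("indel_proximity")
    return reasons


def apply_somatic_filters(
    records: Sequence[VariantRecord],
    matched_normal: bool,
    config: VariantConfig | None = None,
    control_variants: Iterable[tuple[str, int]] = (),
) -> tuple[list[FilterVerdict], pd.DataFrame]:
    """Grade every record against the somatic rule set.

    *control_variants* are (chrom, pos) positions called in the matched
    control, used by the indel-proximity rule. Returns the verdict list
    (aligned with *records*) and a per-rule attrition table with columns
    ``rule`` and ``n_failed`` plus a final ``pass`` row.
    """
    cfg = config or VariantConfig()
    control_index: dict[str, list[int]] = {}
    for chrom, pos in control_variants:
        control_index.setdefault(normalize_chrom(chrom), []).append(int(pos))
    verdicts = []
    for rec in records:
        if matched_normal and not rec.has_normal:
            raise ValidationError(
                f"matched normal expected but record {rec.chrom}:{rec.pos} has no normal fields"
            )
        reasons = _somatic_reasons(rec, matched_normal, cfg, control_index)
        verdicts.append(FilterVerdict(passed=not reasons, reasons=reasons, grade="somatic"))
    rows = [
        {"rule": rule, "n_failed": sum(rule in v.reasons for v in verdicts)} for rule in SOMATIC_RULES
    ]
    rows.append({"rule": "pass", "n_failed": sum(v.passed for v in verdicts)})
    return verdicts, pd.DataFrame(rows)


def signature_grade_filter(
    records: Sequence[VariantRecord], config: VariantConfig | None = None
) -> list[FilterVerdict]:
    """Signature-grade filter on somatic-passing substitutions.

    Requires matched normals; records without one are excluded (verdict
    reason ``no_matched_normal``). Indel input is a caller error.
    """
    cfg = config or VariantConfig()
    verdicts = []
    for rec in records:
        if rec.vtype != "snv":
            raise ValidationError(
                f"signature-grade filter applies to substitutions only ({rec.chrom}:{rec.pos} is an indel)"
            )
        if not rec.has_normal:
            verdicts.append(FilterVerdict(False, ["no_matched_normal"], grade="signature_grade"))
            continue
        reasons = []
        if rec.normal_gq is None or rec.normal_gq < cfg.signature_normal_gq:
            reasons.append("normal_gq")
        if rec.tumour_gq is None or rec.tumour_gq < cfg.signature_tumour_gq:
            reasons.append("tumour_gq")
        verdicts.append(FilterVerdict(not reasons, reasons, grade="signature_grade"))
    return verdicts


def driver_report(
    records: Sequence[VariantRecord],
    matched_normal: bool,
    driver_genes: Iterable[str] | None = None,
    config: VariantConfig | None = None,
) -> pd.DataFrame:
    """Candidate driver mutations among passing records.

    Keeps records whose annotation class is one of the non-synonymous driver
    classes; without a matched normal the report is additionally restricted
    to the supplied driver-gene list (required in that case).
    """
    cfg = config or VariantConfig()
    classes = set(cfg.driver_classes)
    if not matched_normal:
        if driver_genes is None:
            raise ConfigurationError("driver-gene list required for samples without matched normals")
        driver_set = set(driver_genes)
    rows = []
    for rec in records:
        if rec.annotation_class is None or rec.annotation_class not in classes:
            continue
        if not matched_normal and (rec.gene is None or rec.gene not in driver_set):
            continue
        rows.append(
            {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "gene": rec.gene,
                "annotation_class": rec.annotation_class,
                "vaf": rec.tumour_vaf,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", "annotation_class", "vaf"])
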