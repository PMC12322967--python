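"""Tumor-call filtering against the germline-banner criteria.

A call is a potential pathogenic germline variant (PPGV) iff it is
(i) in one of the 24 banner genes, (ii) at or above the specimen-specific VAF
threshold, and (iii) present in the ClinVar snapshot with an evidence-sufficient
P/LP classification.  Filters apply in that fixed order; the first failure
names the single reason.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clinvar_snapshot_io import SnapshotTable, VariantKey
from .evidence_classification import BannerClass, BannerEvidence, SignificanceFamily, classify_evidence

__all__ = [
    "Specimen",
    "Ancestry",
    "SampleMeta",
    "TumorVariantCall",
    "FilterReason",
    "PPGVDecision",
    "BannerConfig",
    "DEFAULT_GENE_PANEL",
    "call_ppgv",
    "call_ppgv_batch",
    "sample_ppgv_status",
    "read_calls_tsv",
    "read_samples_tsv",
    "write_decisions_tsv",
    "read_decisions_tsv",
]

#: The 24 cancer-susceptibility genes highlighted by the germline banner.
DEFAULT_GENE_PANEL: frozenset[str] = frozenset(
    {
        "ATM", "BAP1", "BRCA1", "BRCA2", "BRIP1", "CHEK2", "FH", "FLCN",
        "MLH1", "MSH2", "MSH6", "MUTYH", "PALB2", "PMS2", "POLE", "RAD51C",
        "RAD51D", "RET", "SDHA", "SDHB", "SDHC", "SDHD", "TSC2", "VHL",
    }
)


class Specimen(str, enum.Enum):
    TISSUE = "TISSUE"
    LIQUID = "LIQUID"


class Ancestry(str, enum.Enum):
    AFR = "AFR"
    AMR = "AMR"
    EAS = "EAS"
    EUR = "EUR"
    SAS = "SAS"
    UNKNOWN = "UNKNOWN"


class FilterReason(str, enum.Enum):
    PASS = "PASS"
    FAIL_GENE = "FAIL_GENE"
    FAIL_VAF = "FAIL_VAF"
    FAIL_NOT_IN_CLINVAR = "FAIL_NOT_IN_CLINVAR"
    FAIL_VUS = "FAIL_VUS"
    FAIL_PLP_INSUFFICIENT = "FAIL_PLP_INSUFFICIENT"
    FAIL_BLB = "FAIL_BLB"


#: Reasons attributable to the ClinVar-evidence stage (used for Fig-3B-style
#: decompositions: calls that already passed the gene and VAF filters).
CLINVAR_STAGE_REASONS = frozenset(
    {
        FilterReason.PASS,
        FilterReason.FAIL_NOT_IN_CLINVAR,
        FilterReason.FAIL_VUS,
        FilterReason.FAIL_PLP_INSUFFICIENT,
        FilterReason.FAIL_BLB,
    }
)


@dataclass(frozen=True, slots=True)
class SampleMeta:
    sample_id: str
    specimen: Specimen
    cancer_type: str
    ancestry: Ancestry = Ancestry.UNKNOWN


@dataclass(frozen=True, slots=True)
class TumorVariantCall:
    sample_id: str
    gene: str
    key: VariantKey
    vaf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF must be in [0, 1], got {self.vaf}")


@dataclass(frozen=True, slots=True)
class PPGVDecision:
    call: TumorVariantCall
    is_ppgv: bool
    reason: FilterReason
    evidence: BannerEvidence | None = None

    def __post_init__(self) -> None:
        if self.is_ppgv != (self.reason is FilterReason.PASS):
            raise ValueError("is_ppgv must hold exactly when reason is PASS")


@dataclass(frozen=True)
class BannerConfig:
    """Banner criteria: gene panel plus specimen-specific VAF thresholds."""

    gene_panel: frozenset[str] = DEFAULT_GENE_PANEL
    vaf_threshold_tissue: float = 0.10
    vaf_threshold_liquid: float = 0.30

    def __post_init__(self) -> None:
        if not self.gene_panel:
            raise ValueError("gene_panel must be non-empty")
        if not 0.0 < self.vaf_threshold_tissue <= self.vaf_threshold_liquid < 1.0:
            raise ValueError(
                "require 0 < vaf_threshold_tissue <= vaf_threshold_liquid < 1, got "
                f"{self.vaf_threshold_tissue} / {self.vaf_threshold_liquid}"
            )

    def vaf_threshold(self, specimen: Specimen) -> float:
        if specimen is Specimen.TISSUE:
            return self.vaf_threshold_tissue
        if specimen is Specimen.LIQUID:
            return self.vaf_threshold_liquid
        raise ValueError(f"unknown specimen type {specimen!r}")


def call_ppgv(
    call: TumorVariantCall,
    meta: SampleMeta,
    snapshot: SnapshotTable,
    config: BannerConfig | None = None,
) -> PPGVDecision:
    """Apply the banner filters to one call; thresholds are inclusive (>=).

    Snapshot matching is exact on (chrom, pos, ref, alt); the gene label on the
    call is advisory once the gene filter has passed.
    """
    config = config or BannerConfig()
    if call.sample_id != meta.sample_id:
        raise ValueError(
            f"call sample {call.sample_id!r} does not match metadata sample {meta.sample_id!r}"
        )
    if call.gene not in config.gene_panel:
        return PPGVDecision(call=call, is_ppgv=False, reason=FilterReason.FAIL_GENE)
    if call.vaf < config.vaf_threshold(meta.specimen):
        return PPGVDecision(call=call, is_ppgv=False, reason=FilterReason.FAIL_VAF)
    record = snapshot.records.get(call.key)
    if record is None:
        return PPGVDecision(call=call, is_ppgv=False, reason=FilterReason.FAIL_NOT_IN_CLINVAR)
    evidence = classify_evidence(record)
    if evidence.banner_class is BannerClass.PLP:
        return PPGVDecision(call=call, is_ppgv=True, reason=FilterReason.PASS, evidence=evidence)
    if evidence.banner_class is BannerClass.BLB:
        return PPGVDecision(call=call, is_ppgv=False, reason=FilterReason.FAIL_BLB, evidence=evidence)
    if evidence.significance_family is SignificanceFamily.PATHOGENIC_FAMILY:
        return PPGVDecision(
            call=call, is_ppgv=False, reason=FilterReason.FAIL_PLP_INSUFFICIENT, evidence=evidence
        )
    return PPGVDecision(call=call, is_ppgv=False, reason=FilterReason.FAIL_VUS, evidence=evidence)


def call_ppgv_batch(
    calls: Sequence[TumorVariantCall],
    cohort: Iterable[SampleMeta],
    snapshot: SnapshotTable,
    config: BannerConfig | None = None,
) -> list[PPGVDecision]:
    """Decide every call; each call's sample must exist in the cohort."""
    by_id = _index_cohort(cohort)
    decisions = []
    for call in calls:
        meta = by_id.get(call.sample_id)
        if meta is None:
            raise KeyError(f"call references unknown sample {call.sample_id!r}")
        decisions.append(call_ppgv(call, meta, snapshot, config))
    return decisions


def _index_cohort(cohort: Iterable[SampleMeta]) -> dict[str, SampleMeta]:
    by_id: dict[str, SampleMeta] = {}
    for meta in cohort:
        if meta.sample_id in by_id:
            raise ValueError(f"duplicate sample_id {meta.sample_id!r} in cohort")
        by_id[meta.sample_id] = meta
    return by_id


def sample_ppgv_status(
    decisions: Sequence[PPGVDecision],
    cohort: Sequence[SampleMeta],
) -> pd.DataFrame:
    """Per-sample PPGV status: positive iff >=1 PASS decision.

    Returns one row per cohort sample (samples with no calls are negative),
    with columns ``sample_id``, ``ppgv_positive``, ``n_calls``, ``n_pass``.
    """
    by_id = _index_cohort(cohort)
    n_calls = {sid: 0 for sid in by_id}
    n_pass = {sid: 0 for sid in by_id}
    for dec in decisions:
        sid = dec.call.sample_id
        if sid not in by_id:
            raise KeyError(f"decision references unknown sample {sid!r}")
        n_calls[sid] += 1
        if dec.reason is FilterReason.PASS:
            n_pass[sid] += 1
    rows = [
        {
            "sample_id": sid,
            "ppgv_positive": n_pass[sid] > 0,
            "n_calls": n_calls[sid],
            "n_pass": n_pass[sid],
        }
        for sid in by_id
    ]
    return pd.DataFrame(rows, columns=["sample_id", "ppgv_positive", "n_calls", "n_pass"])


# ---------------------------------------------------------------------------
# Tabular I/O

_CALL_COLUMNS = ["sample_id", "specimen", "gene", "chrom", "pos", "ref", "alt", "vaf"]
_SAMPLE_COLUMNS = ["sample_id", "specimen", "cancer_type", "ancestry"]


def read_calls_tsv(path: str | Path) -> list[TumorVariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: calls table missing columns {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            key = VariantKey(chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt)
            calls.append(
                TumorVariantCall(
                    sample_id=str(row.sample_id), gene=row.gene, key=key, vaf=float(row.vaf)
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return calls


def read_samples_tsv(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = set(_SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: samples table missing columns {sorted(missing)}")
    cohort = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cohort.append(
                SampleMeta(
                    sample_id=str(row.sample_id),
                    specimen=Specimen(row.specimen),
                    cancer_type=str(row.cancer_type),
                    ancestry=Ancestry(row.ancestry),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return cohort


def decisions_to_frame(decisions: Sequence[PPGVDecision]) -> pd.DataFrame:
    rows = []
    for dec in decisions:
        rows.append(
            {
                "sample_id": dec.call.sample_id,
                "gene": dec.call.gene,
                "chrom": dec.call.key.chrom,
                "pos": dec.call.key.pos,
                "ref": dec.call.key.ref,
                "alt": dec.call.key.alt,
                "vaf": dec.call.vaf,
                "is_ppgv": dec.is_ppgv,
                "reason": dec.reason.value,
                "banner_class": dec.evidence.banner_class.value if dec.evidence else "",
                "evidence_detail": dec.evidence.detail.value if dec.evidence else "",
                "significance_family": dec.evidence.significance_family.value if dec.evidence else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "gene", "chrom", "pos", "ref", "alt", "vaf",
            "is_ppgv", "reason", "banner_class", "evidence_detail", "significance_family",
        ],
    )


def write_decisions_tsv(decisions: Sequence[PPGVDecision], path: str | Path) -> None:
    decisions_to_frame(decisions).to_csv(path, sep="\t", index=False)


def decisions_from_frame(df: pd.DataFrame) -> list[PPGVDecision]:
    """Rebuild decision objects from a decisions table (inverse of
    :func:`decisions_to_frame`)."""
    from .evidence_classification import BannerClass, BannerEvidence, EvidenceDetail, SignificanceFamily

    decisions = []
    for row in df.itertuples(index=False):
        key = VariantKey(chrom=str(row.chrom), pos=int(row.pos), ref=row.ref, alt=row.alt)
        call = TumorVariantCall(sample_id=str(row.sample_id), gene=row.gene, key=key,
                                vaf=float(row.vaf))
        evidence = None
        if row.banner_class:
            evidence = BannerEvidence(
                banner_class=BannerClass(row.banner_class),
                detail=EvidenceDetail(row.evidence_detail),
                significance_family=SignificanceFamily(row.significance_family),
            )
        reason = FilterReason(row.reason)
        decisions.append(
            PPGVDecision(call=call, is_ppgv=(reason is FilterReason.PASS),
                         reason=reason, evidence=evidence)
        )
    return decisions


def read_decisions_tsv(path: str | Path) -> pd.DataFrame:
    """Read a decisions table back as a DataFrame (for cohort reporting)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str}, keep_default_na=False)
    df["is_ppgv"] = df["is_ppgv"].astype(bool) if df["is_ppgv"].dtype != object else df["is_ppgv"].map(
        {"True": True, "False": False, True: True, False: False}
    )
    return df
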