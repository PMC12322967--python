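"""Ground-truth-bearing generators for snapshot pairs and tumor cohorts.

Every downstream stage is testable without any external download: the
generators emit syntactically valid ClinVar-dialect VCFs and calls/samples
tables whose true carrier status, planted variants and evidence tiers are
recorded in a ground-truth object.

Synthetic coordinates live in reserved per-gene blocks on chromosome 1 rather
than real transcripts; genomic plausibility is a non-goal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .clinvar_snapshot_io import ClinVarRecord, SnapshotTable, VariantKey
from .evidence_classification import (
    BannerClass,
    EvidenceDetail,
    SignificanceFamily,
    classify_evidence,
)
from .ppgv_caller import (
    Ancestry,
    DEFAULT_GENE_PANEL,
    SampleMeta,
    Specimen,
    TumorVariantCall,
)

__all__ = [
    "SnapshotSimConfig",
    "CohortSimConfig",
    "SnapshotGroundTruth",
    "CohortGroundTruth",
    "gen_snapshot_pair",
    "gen_cohort",
    "write_clinvar_vcf",
    "write_calls_tsv",
    "write_samples_tsv",
    "load_scenario",
    "demo_scenario",
]

#: Spellings emitted per significance family (2022- and 2024-era dialects).
_CLNSIG_SPELLINGS: dict[SignificanceFamily, tuple[str, ...]] = {
    SignificanceFamily.PATHOGENIC_FAMILY: (
        "Pathogenic", "Likely_pathogenic", "Pathogenic/Likely_pathogenic",
    ),
    SignificanceFamily.BENIGN_FAMILY: (
        "Benign", "Likely_benign", "Benign/Likely_benign",
    ),
    SignificanceFamily.UNCERTAIN_FAMILY: ("Uncertain_significance",),
    SignificanceFamily.CONFLICTING_FAMILY: (
        "Conflicting_interpretations_of_pathogenicity",
        "Conflicting_classifications_of_pathogenicity",
    ),
    SignificanceFamily.OTHER_FAMILY: ("not_provided", "drug_response"),
}

_REVSTAT_SPELLINGS: dict[EvidenceDetail, tuple[str, ...]] = {
    EvidenceDetail.EXPERT_PANEL: ("reviewed_by_expert_panel", "practice_guideline"),
    EvidenceDetail.MULTIPLE_SUBMITTERS_NO_CONFLICTS: (
        "criteria_provided,_multiple_submitters,_no_conflicts",
    ),
    EvidenceDetail.SINGLE_SUBMITTER: ("criteria_provided,_single_submitter",),
    EvidenceDetail.CONFLICTING: (
        "criteria_provided,_conflicting_interpretations",
        "criteria_provided,_conflicting_classifications",
    ),
    EvidenceDetail.NO_ASSERTION_CRITERIA: ("no_assertion_criteria_provided",),
    EvidenceDetail.OTHER: ("no_classification_provided",),
}

_GENE_BLOCK = 10_000_000  # coordinates reserved per gene on chromosome 1
_COHORT_OFFSET = 5_000_000  # sub-block for cohort-only (absent) variants
_BASES = ("A", "C", "G", "T")


Cell = tuple[str, SignificanceFamily, EvidenceDetail]


@dataclass(frozen=True)
class SnapshotSimConfig:
    """Baseline cell counts plus growth (novel records and detail upgrades)."""

    baseline: Mapping[Cell, int]
    novel: Mapping[Cell, int] = field(default_factory=dict)
    #: (gene, family, detail_from, detail_to) -> number of records to upgrade.
    upgrades: Mapping[tuple[str, SignificanceFamily, EvidenceDetail, EvidenceDetail], int] = field(
        default_factory=dict
    )
    label_a: str = "snapshot_a"
    label_b: str = "snapshot_b"
    seed: int = 0

    def __post_init__(self) -> None:
        for mapping in (self.baseline, self.novel):
            for cell, count in mapping.items():
                if count < 0:
                    raise ValueError(f"negative count for cell {cell}")
        for cell, count in self.upgrades.items():
            if count < 0:
                raise ValueError(f"negative upgrade count for {cell}")

    def genes(self) -> list[str]:
        return sorted({c[0] for c in self.baseline} | {c[0] for c in self.novel})


@dataclass
class SnapshotGroundTruth:
    """True cell of every emitted record, per snapshot."""

    truth_a: dict[VariantKey, Cell]
    truth_b: dict[VariantKey, Cell]
    novel_keys: set[VariantKey]
    upgraded_keys: dict[VariantKey, tuple[EvidenceDetail, EvidenceDetail]]

    def to_json_dict(self) -> dict:
        def enc(truth: dict[VariantKey, Cell]) -> list:
            return [
                [k.chrom, k.pos, k.ref, k.alt, g, f.value, d.value]
                for k, (g, f, d) in sorted(truth.items(), key=lambda kv: kv[0].sort_key())
            ]

        return {
            "truth_a": enc(self.truth_a),
            "truth_b": enc(self.truth_b),
            "novel_keys": [
                [k.chrom, k.pos, k.ref, k.alt]
                for k in sorted(self.novel_keys, key=VariantKey.sort_key)
            ],
            "upgraded_keys": [
                [k.chrom, k.pos, k.ref, k.alt, d0.value, d1.value]
                for k, (d0, d1) in sorted(
                    self.upgraded_keys.items(), key=lambda kv: kv[0].sort_key()
                )
            ],
        }


def _gene_positions(genes: Sequence[str]) -> dict[str, int]:
    return {g: (i + 1) * _GENE_BLOCK + 1 for i, g in enumerate(sorted(genes))}


def _make_record(
    gene: str,
    family: SignificanceFamily,
    detail: EvidenceDetail,
    pos: int,
    rng: np.random.Generator,
) -> ClinVarRecord:
    ref = _BASES[int(rng.integers(4))]
    alt = _BASES[(( _BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
    key = VariantKey(chrom="1", pos=pos, ref=ref, alt=alt)
    clnsig = _CLNSIG_SPELLINGS[family][int(rng.integers(len(_CLNSIG_SPELLINGS[family])))]
    revstat = _REVSTAT_SPELLINGS[detail][int(rng.integers(len(_REVSTAT_SPELLINGS[detail])))]
    return ClinVarRecord(
        key=key, genes=(gene,), clnsig_raw=clnsig, revstat_raw=revstat, origin_raw="1"
    )


def gen_snapshot_pair(
    config: SnapshotSimConfig, out_dir: str | Path | None = None
) -> tuple[SnapshotTable, SnapshotTable, SnapshotGroundTruth]:
    """Generate snapshot A, snapshot B = A + novel + upgrades, and ground truth.

    Deterministic given the config seed; if ``out_dir`` is given, writes
    ``<label>.vcf`` files that re-read into the same tables.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.genes()
    if not genes:
        raise ValueError("config defines no genes")
    panel = frozenset(genes)
    next_pos = _gene_positions(genes)

    records_a: dict[VariantKey, ClinVarRecord] = {}
    truth_a: dict[VariantKey, Cell] = {}
    cell_members: dict[Cell, list[VariantKey]] = {}
    for cell in sorted(config.baseline, key=lambda c: (c[0], c[1].value, c[2].value)):
        gene, family, detail = cell
        for _ in range(config.baseline[cell]):
            rec = _make_record(gene, family, detail, next_pos[gene], rng)
            next_pos[gene] += 1
            records_a[rec.key] = rec
            truth_a[rec.key] = cell
            cell_members.setdefault(cell, []).append(rec.key)

    # Upgrades: re-annotate selected A records with the higher review tier in B.
    records_b: dict[VariantKey, ClinVarRecord] = dict(records_a)
    truth_b: dict[VariantKey, Cell] = dict(truth_a)
    upgraded: dict[VariantKey, tuple[EvidenceDetail, EvidenceDetail]] = {}
    for spec in sorted(config.upgrades, key=lambda c: (c[0], c[1].value, c[2].value, c[3].value)):
        gene, family, detail_from, detail_to = spec
        count = config.upgrades[spec]
        pool = [k for k in cell_members.get((gene, family, detail_from), []) if k not in upgraded]
        if count > len(pool):
            raise ValueError(
                f"upgrade of {count} records requested from cell "
                f"({gene}, {family.value}, {detail_from.value}) holding {len(pool)}"
            )
        chosen_idx = rng.choice(len(pool), size=count, replace=False)
        for i in sorted(int(j) for j in chosen_idx):
            key = pool[i]
            old = records_b[key]
            new_revstat = _REVSTAT_SPELLINGS[detail_to][0]
            records_b[key] = ClinVarRecord(
                key=key, genes=old.genes, clnsig_raw=old.clnsig_raw,
                revstat_raw=new_revstat, origin_raw=old.origin_raw,
            )
            truth_b[key] = (gene, family, detail_to)
            upgraded[key] = (detail_from, detail_to)

    novel_keys: set[VariantKey] = set()
    for cell in sorted(config.novel, key=lambda c: (c[0], c[1].value, c[2].value)):
        gene, family, detail = cell
        for _ in range(config.novel[cell]):
            rec = _make_record(gene, family, detail, next_pos[gene], rng)
            next_pos[gene] += 1
            records_b[rec.key] = rec
            truth_b[rec.key] = cell
            novel_keys.add(rec.key)

    snap_a = SnapshotTable(label=config.label_a, records=records_a, gene_panel=panel)
    snap_b = SnapshotTable(label=config.label_b, records=records_b, gene_panel=panel)
    truth = SnapshotGroundTruth(
        truth_a=truth_a, truth_b=truth_b, novel_keys=novel_keys, upgraded_keys=upgraded
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_clinvar_vcf(snap_a, out_dir / f"{config.label_a}.vcf")
        write_clinvar_vcf(snap_b, out_dir / f"{config.label_b}.vcf")
    return snap_a, snap_b, truth


def write_clinvar_vcf(snapshot: SnapshotTable, path: str | Path) -> None:
    """Write a snapshot as a minimal but well-formed ClinVar-dialect VCF."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.1\n")
        fh.write('##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">\n')
        fh.write('##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="Review status">\n')
        fh.write('##INFO=<ID=GENEINFO,Number=1,Type=String,Description="Gene symbol:id pairs">\n')
        fh.write('##INFO=<ID=ORIGIN,Number=.,Type=String,Description="Allele origin">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, rec in enumerate(snapshot.sorted_records(), start=1):
            info = []
            if rec.clnsig_raw:
                info.append(f"CLNSIG={rec.clnsig_raw}")
            if rec.revstat_raw:
                info.append(f"CLNREVSTAT={rec.revstat_raw}")
            info.append("GENEINFO=" + "|".join(f"{g}:{1000 + j}" for j, g in enumerate(rec.genes)))
            if rec.origin_raw is not None:
                info.append(f"ORIGIN={rec.origin_raw}")
            fh.write(
                f"{rec.key.chrom}\t{rec.key.pos}\t{i}\t{rec.key.ref}\t{rec.key.alt}"
                f"\t.\t.\t{';'.join(info)}\n"
            )


# ---------------------------------------------------------------------------
# Cohort generator


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort composition and the per-ancestry generative parameters.

    ``carrier_rate`` is the true germline carrier probability per ancestry;
    ``representation`` is the probability that a carried pathogenic-family
    variant appears in the snapshot with banner-sufficient evidence.  Carriers
    not covered by the representation probability split evenly between a
    variant absent from the snapshot and one present without sufficient
    evidence.
    """

    n_samples: Mapping[tuple[str, str, str], int]  # (specimen, cancer_type, ancestry) -> n
    carrier_rate: Mapping[str, float]
    representation: Mapping[str, float]
    germline_vaf_mean: float = 0.5
    germline_vaf_sd: float = 0.1
    somatic_vaf_min: float = 0.01
    somatic_vaf_max: float = 0.45
    background_rate: float = 1.0
    offpanel_fraction: float = 0.3
    offpanel_gene: str = "OFFPANEL1"
    seed: int = 0

    def __post_init__(self) -> None:
        for mapping in (self.carrier_rate, self.representation):
            for anc, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability out of [0,1] for {anc}: {p}")
        for cell, n in self.n_samples.items():
            if n < 0:
                raise ValueError(f"negative cell count for {cell}")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")


@dataclass
class CohortGroundTruth:
    """Per-sample carrier flags and planted variants, plus the parameters used."""

    carrier: dict[str, bool]
    planted_key: dict[str, VariantKey]
    planted_kind: dict[str, str]  # "sufficient" | "insufficient" | "absent"
    carrier_rate: dict[str, float]
    representation: dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "carrier": self.carrier,
            "planted": {
                sid: [k.chrom, k.pos, k.ref, k.alt, self.planted_kind[sid]]
                for sid, k in self.planted_key.items()
            },
            "carrier_rate": self.carrier_rate,
            "representation": self.representation,
        }


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    # Rejection sampling keeps the draw stream simple and deterministic.
    while True:
        x = rng.normal(mean, sd)
        if 0.0 <= x <= 1.0:
            return x


def gen_cohort(
    config: CohortSimConfig,
    snapshot: SnapshotTable,
    out_dir: str | Path | None = None,
) -> tuple[list[TumorVariantCall], list[SampleMeta], CohortGroundTruth]:
    """Generate tumor calls and sample metadata against ``snapshot``.

    Deterministic given the config seed.  Background somatic calls (low VAF,
    or off-panel genes, never matching a snapshot key) provide FAIL_VAF and
    FAIL_GENE traffic.
    """
    rng = np.random.default_rng(config.seed)

    sufficient: list[tuple[VariantKey, str]] = []
    insufficient: list[tuple[VariantKey, str]] = []
    for rec in snapshot.sorted_records():
        ev = classify_evidence(rec)
        gene = rec.panel_genes(snapshot.gene_panel)[0]
        if ev.banner_class is BannerClass.PLP:
            sufficient.append((rec.key, gene))
        elif ev.significance_family is SignificanceFamily.PATHOGENIC_FAMILY:
            insufficient.append((rec.key, gene))

    panel_genes = sorted(snapshot.gene_panel)
    gene_base = _gene_positions(panel_genes)
    absent_pos = {g: gene_base[g] + _COHORT_OFFSET for g in panel_genes}
    offpanel_pos = [90_000_000]  # chromosome 22 block for off-panel traffic

    def fabricate_absent(gene: str) -> VariantKey:
        key = VariantKey(chrom="1", pos=absent_pos[gene], ref="A", alt="T")
        absent_pos[gene] += 1
        return key

    def fabricate_offpanel() -> VariantKey:
        key = VariantKey(chrom="22", pos=offpanel_pos[0], ref="G", alt="C")
        offpanel_pos[0] += 1
        return key

    samples: list[SampleMeta] = []
    calls: list[TumorVariantCall] = []
    carrier: dict[str, bool] = {}
    planted_key: dict[str, VariantKey] = {}
    planted_kind: dict[str, str] = {}

    sid_counter = 0
    cells = sorted(config.n_samples.items())
    for (specimen_s, cancer_type, ancestry_s), n in cells:
        specimen = Specimen(specimen_s)
        ancestry = Ancestry(ancestry_s)
        pi = config.carrier_rate.get(ancestry_s, 0.0)
        rho = config.representation.get(ancestry_s, 0.0)
        for _ in range(n):
            sid_counter += 1
            sid = f"S{sid_counter:07d}"
            samples.append(
                SampleMeta(sample_id=sid, specimen=specimen, cancer_type=cancer_type,
                           ancestry=ancestry)
            )
            is_carrier = bool(rng.random() < pi)
            carrier[sid] = is_carrier
            if is_carrier:
                if rng.random() < rho:
                    if not sufficient:
                        raise ValueError(
                            "representation > 0 requires banner-sufficient P/LP records "
                            "in the snapshot"
                        )
                    key, gene = sufficient[int(rng.integers(len(sufficient)))]
                    kind = "sufficient"
                elif insufficient and rng.random() < 0.5:
                    key, gene = insufficient[int(rng.integers(len(insufficient)))]
                    kind = "insufficient"
                else:
                    gene = panel_genes[int(rng.integers(len(panel_genes)))]
                    key = fabricate_absent(gene)
                    kind = "absent"
                vaf = round(_truncated_normal(rng, config.germline_vaf_mean,
                                              config.germline_vaf_sd), 6)
                calls.append(TumorVariantCall(sample_id=sid, gene=gene, key=key, vaf=vaf))
                planted_key[sid] = key
                planted_kind[sid] = kind
            if config.background_rate > 0:
                for _ in range(int(rng.poisson(config.background_rate))):
                    vaf = round(float(rng.uniform(config.somatic_vaf_min,
                                                  config.somatic_vaf_max)), 6)
                    if rng.random() < config.offpanel_fraction:
                        calls.append(
                            TumorVariantCall(sample_id=sid, gene=config.offpanel_gene,
                                             key=fabricate_offpanel(), vaf=vaf)
                        )
                    else:
                        gene = panel_genes[int(rng.integers(len(panel_genes)))]
                        calls.append(
                            TumorVariantCall(sample_id=sid, gene=gene,
                                             key=fabricate_absent(gene), vaf=vaf)
                        )

    truth = CohortGroundTruth(
        carrier=carrier,
        planted_key=planted_key,
        planted_kind=planted_kind,
        carrier_rate=dict(config.carrier_rate),
        representation=dict(config.representation),
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_calls_tsv(calls, samples, out_dir / "calls.tsv")
        write_samples_tsv(samples, out_dir / "samples.tsv")
        with open(out_dir / "ground_truth.json", "wt", encoding="utf-8") as fh:
            json.dump(truth.to_json_dict(), fh, indent=2, sort_keys=True)
    return calls, samples, truth


def write_calls_tsv(
    calls: Sequence[TumorVariantCall], samples: Sequence[SampleMeta], path: str | Path
) -> None:
    specimen_by_sid = {m.sample_id: m.specimen.value for m in samples}
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tspecimen\tgene\tchrom\tpos\tref\talt\tvaf\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{specimen_by_sid[c.sample_id]}\t{c.gene}\t"
                f"{c.key.chrom}\t{c.key.pos}\t{c.key.ref}\t{c.key.alt}\t{c.vaf:.6f}\n"
            )


def write_samples_tsv(samples: Sequence[SampleMeta], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tspecimen\tcancer_type\tancestry\n")
        for m in samples:
            fh.write(f"{m.sample_id}\t{m.specimen.value}\t{m.cancer_type}\t{m.ancestry.value}\n")


# ---------------------------------------------------------------------------
# Scenario files


def load_scenario(path: str | Path) -> tuple[SnapshotSimConfig, CohortSimConfig]:
    """Load a YAML simulation scenario (see ``demo_scenario`` for the schema)."""
    import yaml

    with open(path, "rt", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    seed = int(doc.get("seed", 0))
    snap = doc["snapshot"]

    def cells(entries) -> dict[Cell, int]:
        out: dict[Cell, int] = {}
        for e in entries or []:
            cell = (e["gene"], SignificanceFamily(e["family"]), EvidenceDetail(e["detail"]))
            out[cell] = out.get(cell, 0) + int(e["count"])
        return out

    upgrades = {}
    for e in snap.get("upgrades") or []:
        key = (
            e["gene"],
            SignificanceFamily(e["family"]),
            EvidenceDetail(e["from"]),
            EvidenceDetail(e["to"]),
        )
        upgrades[key] = upgrades.get(key, 0) + int(e["count"])
    snap_cfg = SnapshotSimConfig(
        baseline=cells(snap.get("baseline")),
        novel=cells(snap.get("novel")),
        upgrades=upgrades,
        label_a=str(snap.get("label_a", "snapshot_a")),
        label_b=str(snap.get("label_b", "snapshot_b")),
        seed=seed,
    )

    coh = doc["cohort"]
    n_samples = {}
    for e in coh["n_samples"]:
        cell = (e["specimen"], e["cancer_type"], e["ancestry"])
        n_samples[cell] = n_samples.get(cell, 0) + int(e["count"])
    cohort_cfg = CohortSimConfig(
        n_samples=n_samples,
        carrier_rate={k: float(v) for k, v in coh["carrier_rate"].items()},
        representation={k: float(v) for k, v in coh["representation"].items()},
        germline_vaf_mean=float(coh.get("germline_vaf_mean", 0.5)),
        germline_vaf_sd=float(coh.get("germline_vaf_sd", 0.1)),
        somatic_vaf_min=float(coh.get("somatic_vaf_min", 0.01)),
        somatic_vaf_max=float(coh.get("somatic_vaf_max", 0.45)),
        background_rate=float(coh.get("background_rate", 1.0)),
        offpanel_fraction=float(coh.get("offpanel_fraction", 0.3)),
        offpanel_gene=str(coh.get("offpanel_gene", "OFFPANEL1")),
        seed=seed + 1,
    )
    return snap_cfg, cohort_cfg


def demo_scenario(seed: int = 0) -> tuple[SnapshotSimConfig, CohortSimConfig]:
    """A small built-in scenario exercising every pipeline stage."""
    genes = sorted(DEFAULT_GENE_PANEL)
    baseline: dict[Cell, int] = {}
    novel: dict[Cell, int] = {}
    upgrades: dict[tuple[str, SignificanceFamily, EvidenceDetail, EvidenceDetail], int] = {}
    for gene in genes:
        baseline[(gene, SignificanceFamily.PATHOGENIC_FAMILY,
                  EvidenceDetail.MULTIPLE_SUBMITTERS_NO_CONFLICTS)] = 20
        baseline[(gene, SignificanceFamily.PATHOGENIC_FAMILY, EvidenceDetail.SINGLE_SUBMITTER)] = 15
        baseline[(gene, SignificanceFamily.BENIGN_FAMILY,
                  EvidenceDetail.MULTIPLE_SUBMITTERS_NO_CONFLICTS)] = 20
        baseline[(gene, SignificanceFamily.UNCERTAIN_FAMILY, EvidenceDetail.SINGLE_SUBMITTER)] = 120
        baseline[(gene, SignificanceFamily.CONFLICTING_FAMILY, EvidenceDetail.CONFLICTING)] = 10
        novel[(gene, SignificanceFamily.UNCERTAIN_FAMILY, EvidenceDetail.SINGLE_SUBMITTER)] = 60
        novel[(gene, SignificanceFamily.PATHOGENIC_FAMILY, EvidenceDetail.SINGLE_SUBMITTER)] = 25
        novel[(gene, SignificanceFamily.PATHOGENIC_FAMILY,
               EvidenceDetail.MULTIPLE_SUBMITTERS_NO_CONFLICTS)] = 3
        novel[(gene, SignificanceFamily.BENIGN_FAMILY,
               EvidenceDetail.MULTIPLE_SUBMITTERS_NO_CONFLICTS)] = 12
        upgrades[(gene, SignificanceFamily.PATHOGENIC_FAMILY,
                  EvidenceDetail.SINGLE_SUBMITTER,
                  EvidenceDetail.MULTIPLE_SUBMITTERS_NO_CONFLICTS)] = 5
    snap_cfg = SnapshotSimConfig(
        baseline=baseline, novel=novel, upgrades=upgrades,
        label_a="sim2022", label_b="sim2024", seed=seed,
    )

    n_samples = {}
    for ancestry, n in [("EUR", 1500), ("AFR", 400), ("AMR", 400), ("EAS", 400), ("SAS", 300)]:
        n_samples[("TISSUE", "breast", ancestry)] = n // 2
        n_samples[("TISSUE", "colorectal", ancestry)] = n // 4
        n_samples[("LIQUID", "lung", ancestry)] = n // 4
    cohort_cfg = CohortSimConfig(
        n_samples=n_samples,
        carrier_rate={a: 0.12 for a in ("EUR", "AFR", "AMR", "EAS", "SAS")},
        representation={"EUR": 0.95, "AFR": 0.75, "AMR": 0.8, "EAS": 0.8, "SAS": 0.78},
        background_rate=1.0,
        seed=seed + 1,
    )
    return snap_cfg, cohort_cfg
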