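"""End-to-end orchestration: classify -> diff -> call-ppgv -> cohort-report.

All outputs are plain TSV and JSON so every figure-level quantity can be
audited from text files.  A manifest records inputs, config and seeds;
re-running with identical inputs and seeds reproduces identical result files
(the manifest's own timestamp is the only run-specific value).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .clinvar_snapshot_io import SnapshotTable, read_clinvar_vcf
from .cohort_analysis import (
    decomposition_disparity_tests,
    filter_decomposition,
    gene_ppgv_counts,
    prevalence_compare,
    prevalence_disparity_tests,
)
from .ppgv_caller import (
    BannerConfig,
    FilterReason,
    PPGVDecision,
    SampleMeta,
    TumorVariantCall,
    call_ppgv_batch,
    sample_ppgv_status,
    write_decisions_tsv,
)
from .snapshot_evolution import diff_snapshots, novel_evidence_breakdown, novel_variants

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "RunManifest", "run_full_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline settings: banner criteria plus reporting options."""

    banner: BannerConfig = field(default_factory=BannerConfig)
    novel_genes: tuple[str, ...] = ("BRCA1", "BRCA2")
    alpha: float = 0.05
    germline_origin_only: bool = False

    def to_dict(self) -> dict:
        return {
            "gene_panel": sorted(self.banner.gene_panel),
            "vaf_threshold_tissue": self.banner.vaf_threshold_tissue,
            "vaf_threshold_liquid": self.banner.vaf_threshold_liquid,
            "novel_genes": list(self.novel_genes),
            "alpha": self.alpha,
            "germline_origin_only": self.germline_origin_only,
        }


@dataclass
class RunManifest:
    version: str
    inputs: dict[str, str]  # path -> sha256
    config: dict
    timestamp: str
    seeds: dict[str, int]

    def write(self, path: Path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _reason_counts(decisions: Sequence[PPGVDecision]) -> dict[str, int]:
    counts: dict[str, int] = {r.value: 0 for r in FilterReason}
    for dec in decisions:
        counts[dec.reason.value] += 1
    return counts


def run_full_analysis(
    snapshot_a_path: str | Path,
    snapshot_b_path: str | Path,
    calls: Sequence[TumorVariantCall],
    cohort: Sequence[SampleMeta],
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    seeds: Mapping[str, int] | None = None,
) -> Path:
    """Run every stage and write the analysis artifacts into ``out_dir``."""
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = config.banner.gene_panel

    logger.info("reading snapshots")
    snap_a = read_clinvar_vcf(snapshot_a_path, panel,
                              germline_origin_only=config.germline_origin_only)
    snap_b = read_clinvar_vcf(snapshot_b_path, panel,
                              germline_origin_only=config.germline_origin_only)
    logger.info("snapshot %s: %d records; snapshot %s: %d records",
                snap_a.label, len(snap_a), snap_b.label, len(snap_b))

    # Snapshot evolution
    diff = diff_snapshots(snap_a, snap_b)
    diff.overall_frame().to_csv(out_dir / "diff_overall.tsv", sep="\t", index=False)
    diff.per_gene_frame().to_csv(out_dir / "diff_per_gene.tsv", sep="\t", index=False)
    _dump_json(diff.to_summary(), out_dir / "diff_summary.json")

    novel_genes = tuple(g for g in config.novel_genes if g in panel)
    novel_json: dict = {"genes": list(novel_genes)}
    if novel_genes:
        novel = novel_variants(snap_a, snap_b, novel_genes)
        breakdown = novel_evidence_breakdown(novel, snap_b)
        novel_json.update(
            n_novel=breakdown.n_novel,
            class_fractions=breakdown.class_fractions,
            plp_detail_fractions=breakdown.plp_detail_fractions,
        )
    _dump_json(novel_json, out_dir / "novel_breakdown.json")

    # PPGV calling under each snapshot
    results = {}
    for tag, snap in (("a", snap_a), ("b", snap_b)):
        decisions = call_ppgv_batch(calls, cohort, snap, config.banner)
        logger.info("snapshot %s decision counts: %s", snap.label, _reason_counts(decisions))
        write_decisions_tsv(decisions, out_dir / f"decisions_{tag}.tsv")
        status = sample_ppgv_status(decisions, cohort)
        status.to_csv(out_dir / f"sample_status_{tag}.tsv", sep="\t", index=False)
        gene_ppgv_counts(decisions).to_csv(
            out_dir / f"gene_ppgv_counts_{tag}.tsv", sep="\t", index=False
        )
        decomp = filter_decomposition(decisions, cohort)
        decomp.to_csv(out_dir / f"filter_decomposition_{tag}.tsv", sep="\t", index=False)
        results[tag] = (decisions, status, decomp)

    decisions_a, status_a, decomp_a = results["a"]
    decisions_b, status_b, decomp_b = results["b"]

    # Prevalence comparisons (percentage-point and percent-of-baseline changes)
    for stratum in ("cancer_type", "ancestry", "specimen", "overall"):
        prevalence_compare(status_a, status_b, cohort, stratum).to_csv(
            out_dir / f"prevalence_by_{stratum}.tsv", sep="\t", index=False
        )

    # ClinVar-filtered variant reduction between snapshots (eligible calls
    # excluded at the evidence stage under each snapshot).
    def n_excluded(decisions: Sequence[PPGVDecision]) -> int:
        counts = _reason_counts(decisions)
        return sum(
            counts[r.value]
            for r in (FilterReason.FAIL_NOT_IN_CLINVAR, FilterReason.FAIL_VUS,
                      FilterReason.FAIL_PLP_INSUFFICIENT, FilterReason.FAIL_BLB)
        )

    excl_a, excl_b = n_excluded(decisions_a), n_excluded(decisions_b)
    _dump_json(
        {
            "n_filtered_a": excl_a,
            "n_filtered_b": excl_b,
            "delta": excl_b - excl_a,
            "rel_change_percent": (100.0 * (excl_b - excl_a) / excl_a) if excl_a else None,
            "reason_counts_a": _reason_counts(decisions_a),
            "reason_counts_b": _reason_counts(decisions_b),
        },
        out_dir / "filtered_reduction.json",
    )

    # Ancestry disparity tests under the later snapshot
    tests = {
        "alpha": config.alpha,
        "prevalence": [t.to_dict() for t in
                       prevalence_disparity_tests(status_b, cohort, alpha=config.alpha)],
        "decomposition": [t.to_dict() for t in
                          decomposition_disparity_tests(decisions_b, cohort, alpha=config.alpha)],
    }
    _dump_json(tests, out_dir / "disparity_tests.json")

    manifest = RunManifest(
        version=__version__,
        inputs={
            str(snapshot_a_path): _sha256(Path(snapshot_a_path)),
            str(snapshot_b_path): _sha256(Path(snapshot_b_path)),
        },
        config=config.to_dict(),
        timestamp=datetime.now(timezone.utc).isoformat(),
        seeds=dict(seeds or {}),
    )
    manifest.write(out_dir / "manifest.json")
    return out_dir
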