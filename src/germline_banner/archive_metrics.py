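"""Headline snapshot-evolution metrics computed from two dated ClinVar VCFs.

This is the quantitative core of the two-snapshot comparison: overall and
per-class growth across the 24-gene panel, the VUS share of the later
snapshot, and the evidence mix of novel BRCA1/2 entries.  It works on any pair
of ClinVar-dialect VCF files (real dated pulls or synthetic ones).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .clinvar_snapshot_io import read_clinvar_vcf
from .evidence_classification import EvidenceDetail
from .ppgv_caller import DEFAULT_GENE_PANEL
from .snapshot_evolution import diff_snapshots, novel_evidence_breakdown, novel_variants

__all__ = ["snapshot_evolution_metrics"]


def snapshot_evolution_metrics(
    path_a: str | Path,
    path_b: str | Path,
    gene_panel: Iterable[str] = DEFAULT_GENE_PANEL,
    novel_genes: tuple[str, ...] = ("BRCA1", "BRCA2"),
) -> dict[str, dict[str, float | int]]:
    """Compute the headline metrics between two snapshot files.

    Returns a mapping of metric name to ``{"value": ..., "n": ...}`` where
    percentages are on the 0-100 scale and ``n`` is the record count the
    metric was computed over.

    Metrics
    -------
    - ``total_rel_change``: % change in key-deduplicated record count.
    - ``plp_rel_change`` / ``blb_rel_change`` / ``vus_rel_change``: % change
      per evidence class.
    - ``vus_proportion_b``: VUS share of the later snapshot, in %.
    - ``novel_subset_pathogenic_fraction``: % of novel-subset entries (default
      BRCA1/2) whose aggregate significance is pathogenic-family.
    - ``novel_subset_path_single_submitter_fraction``: % of those
      pathogenic-family novel entries with single-submitter review status.
    - ``subset_total_rel_change``: % change in record count over the subset
      genes alone.
    """
    panel = frozenset(g.upper() for g in gene_panel)
    snap_a = read_clinvar_vcf(path_a, panel, label=Path(path_a).stem)
    snap_b = read_clinvar_vcf(path_b, panel, label=Path(path_b).stem)
    diff = diff_snapshots(snap_a, snap_b)

    out: dict[str, dict[str, float | int]] = {}
    n_total = diff.counts_a["TOTAL"]
    out["total_rel_change"] = {"value": diff.rel_changes["TOTAL"], "n": n_total}
    for cls, name in (("PLP", "plp_rel_change"), ("BLB", "blb_rel_change"),
                      ("VUS", "vus_rel_change")):
        out[name] = {"value": diff.rel_changes[cls], "n": diff.counts_a[cls]}
    out["vus_proportion_b"] = {
        "value": 100.0 * diff.proportions_b["VUS"],
        "n": diff.counts_b["TOTAL"],
    }

    subset = tuple(g.upper() for g in novel_genes)
    novel = novel_variants(snap_a, snap_b, subset)
    breakdown = novel_evidence_breakdown(novel, snap_b)
    if breakdown.class_fractions is not None:
        out["novel_subset_pathogenic_fraction"] = {
            "value": 100.0 * breakdown.class_fractions["PLP"],
            "n": breakdown.n_novel,
        }
    if breakdown.plp_detail_fractions is not None:
        n_path = round(breakdown.n_novel * breakdown.class_fractions["PLP"])
        out["novel_subset_path_single_submitter_fraction"] = {
            "value": 100.0 * breakdown.plp_detail_fractions[EvidenceDetail.SINGLE_SUBMITTER.value],
            "n": n_path,
        }

    def count_subset(snap) -> int:
        return sum(1 for rec in snap.records.values() if set(rec.genes) & set(subset))

    na, nb = count_subset(snap_a), count_subset(snap_b)
    if na > 0:
        out["subset_total_rel_change"] = {"value": 100.0 * (nb - na) / na, "n": na}
    return out
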