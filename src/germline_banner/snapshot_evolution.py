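"""Diffing two snapshots of the same gene panel.

Overall counts de-duplicate by variant key; per-gene tables attribute a
multi-gene record to each panel gene it lists (and therefore may double-count
a record across genes — see output metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .clinvar_snapshot_io import SnapshotTable, VariantKey
from .evidence_classification import (
    BannerClass,
    EvidenceDetail,
    SignificanceFamily,
    classify_evidence,
)

__all__ = [
    "SnapshotDiff",
    "NovelEvidenceBreakdown",
    "diff_snapshots",
    "novel_variants",
    "novel_evidence_breakdown",
]

_CLASSES = (BannerClass.PLP, BannerClass.BLB, BannerClass.VUS)


def _rel_change(a: int, b: int) -> float | None:
    """Relative percent change; None is the "new" sentinel when a == 0 < b."""
    if a == 0:
        return 0.0 if b == 0 else None
    return 100.0 * (b - a) / a


@dataclass(slots=True)
class SnapshotDiff:
    label_a: str
    label_b: str
    #: Per-class counts over key-deduplicated records, plus a "TOTAL" entry.
    counts_a: dict[str, int]
    counts_b: dict[str, int]
    deltas: dict[str, int]
    rel_changes: dict[str, float | None]
    proportions_a: dict[str, float]
    proportions_b: dict[str, float]
    #: gene -> class -> count (multi-gene records counted once per gene).
    per_gene_a: dict[str, dict[str, int]]
    per_gene_b: dict[str, dict[str, int]]

    def overall_frame(self) -> pd.DataFrame:
        rows = []
        for cls in [c.value for c in _CLASSES] + ["TOTAL"]:
            rows.append(
                {
                    "class": cls,
                    "count_a": self.counts_a[cls],
                    "count_b": self.counts_b[cls],
                    "delta": self.deltas[cls],
                    "rel_change_percent": self.rel_changes[cls],
                    "proportion_a": self.proportions_a.get(cls),
                    "proportion_b": self.proportions_b.get(cls),
                }
            )
        return pd.DataFrame(rows)

    def per_gene_frame(self) -> pd.DataFrame:
        genes = sorted(set(self.per_gene_a) | set(self.per_gene_b))
        rows = []
        for gene in genes:
            for cls in (c.value for c in _CLASSES):
                a = self.per_gene_a.get(gene, {}).get(cls, 0)
                b = self.per_gene_b.get(gene, {}).get(cls, 0)
                rows.append(
                    {
                        "gene": gene,
                        "class": cls,
                        "count_a": a,
                        "count_b": b,
                        "delta": b - a,
                        "rel_change_percent": _rel_change(a, b),
                    }
                )
        return pd.DataFrame(rows)

    def to_summary(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "counts_a": self.counts_a,
            "counts_b": self.counts_b,
            "deltas": self.deltas,
            "rel_changes_percent": {
                k: (v if v is not None else "new") for k, v in self.rel_changes.items()
            },
            "proportions_a": self.proportions_a,
            "proportions_b": self.proportions_b,
            "note": "per-gene counts may attribute one record to several panel genes",
        }


def _count_snapshot(snap: SnapshotTable) -> tuple[dict[str, int], dict[str, dict[str, int]]]:
    overall = {c.value: 0 for c in _CLASSES}
    per_gene: dict[str, dict[str, int]] = {}
    for rec in snap.records.values():
        cls = classify_evidence(rec).banner_class.value
        overall[cls] += 1
        for gene in rec.panel_genes(snap.gene_panel):
            per_gene.setdefault(gene, {c.value: 0 for c in _CLASSES})[cls] += 1
    overall["TOTAL"] = len(snap.records)
    return overall, per_gene


def diff_snapshots(a: SnapshotTable, b: SnapshotTable) -> SnapshotDiff:
    """Per-class and per-gene counts, deltas, relative changes, proportions."""
    if a.gene_panel != b.gene_panel:
        raise ValueError(
            f"snapshots restricted to different gene panels: "
            f"{sorted(a.gene_panel)} vs {sorted(b.gene_panel)}"
        )
    counts_a, per_gene_a = _count_snapshot(a)
    counts_b, per_gene_b = _count_snapshot(b)
    keys = [c.value for c in _CLASSES] + ["TOTAL"]
    deltas = {k: counts_b[k] - counts_a[k] for k in keys}
    rel = {k: _rel_change(counts_a[k], counts_b[k]) for k in keys}

    def proportions(counts: dict[str, int]) -> dict[str, float]:
        total = counts["TOTAL"]
        if total == 0:
            return {c.value: 0.0 for c in _CLASSES}
        return {c.value: counts[c.value] / total for c in _CLASSES}

    return SnapshotDiff(
        label_a=a.label,
        label_b=b.label,
        counts_a=counts_a,
        counts_b=counts_b,
        deltas=deltas,
        rel_changes=rel,
        proportions_a=proportions(counts_a),
        proportions_b=proportions(counts_b),
        per_gene_a=per_gene_a,
        per_gene_b=per_gene_b,
    )


def novel_variants(
    a: SnapshotTable, b: SnapshotTable, genes: Iterable[str] | None = None
) -> set[VariantKey]:
    """Keys present in ``b`` (attributed to ``genes``) but absent from ``a``.

    Novelty is pure key set-difference: a pre-existing record whose
    classification changed is not novel.
    """
    if genes is None:
        gene_set = set(b.gene_panel)
    else:
        gene_set = {g.upper() for g in genes}
        extra = gene_set - set(b.gene_panel)
        if extra:
            raise ValueError(f"genes not in the snapshot panel: {sorted(extra)}")
    return {
        key
        for key, rec in b.records.items()
        if key not in a.records and set(rec.genes) & gene_set
    }


@dataclass(slots=True)
class NovelEvidenceBreakdown:
    """Class mix of novel entries, by significance family.

    ``class_fractions`` uses the significance family (pathogenic-family /
    benign-family / everything-else-as-VUS), not the banner class: the novel
    entries of interest are dominated by single-submitter pathogenic
    assertions that the banner rule would fold into VUS.
    ``plp_detail_fractions`` breaks the pathogenic-family novel entries down
    by review-status tier.  Fractions are None when the denominator is empty.
    """

    n_novel: int
    class_fractions: dict[str, float] | None
    plp_detail_fractions: dict[str, float] | None


def novel_evidence_breakdown(
    novel: set[VariantKey], b: SnapshotTable
) -> NovelEvidenceBreakdown:
    missing = novel - set(b.records)
    if missing:
        raise ValueError(f"{len(missing)} novel keys not present in snapshot {b.label}")
    n = len(novel)
    if n == 0:
        return NovelEvidenceBreakdown(n_novel=0, class_fractions=None, plp_detail_fractions=None)
    class_counts = {"PLP": 0, "BLB": 0, "VUS": 0}
    detail_counts: dict[str, int] = {d.value: 0 for d in EvidenceDetail if d is not EvidenceDetail.ABSENT}
    n_path = 0
    for key in novel:
        ev = classify_evidence(b.records[key])
        if ev.significance_family is SignificanceFamily.PATHOGENIC_FAMILY:
            class_counts["PLP"] += 1
            n_path += 1
            detail_counts[ev.detail.value] += 1
        elif ev.significance_family is SignificanceFamily.BENIGN_FAMILY:
            class_counts["BLB"] += 1
        else:
            class_counts["VUS"] += 1
    class_fractions = {k: v / n for k, v in class_counts.items()}
    plp_detail_fractions = (
        {k: v / n_path for k, v in detail_counts.items()} if n_path else None
    )
    return NovelEvidenceBreakdown(
        n_novel=n, class_fractions=class_fractions, plp_detail_fractions=plp_detail_fractions
    )
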