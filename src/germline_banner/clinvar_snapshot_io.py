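"""Reading and writing ClinVar-style VCF snapshots restricted to a gene panel.

The reader keeps the aggregate significance (``CLNSIG``) and review-status
(``CLNREVSTAT``) INFO values verbatim, byte-for-byte, so that every downstream
classification decision can be audited against the source file.  This is why
INFO parsing is done on the raw line rather than through a VCF library: generic
parsers split ``CLNREVSTAT`` values such as
``criteria_provided,_multiple_submitters,_no_conflicts`` on the embedded commas
and the original string is no longer recoverable.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "VariantKey",
    "ClinVarRecord",
    "SnapshotTable",
    "SnapshotFormatError",
    "read_clinvar_vcf",
    "write_snapshot_tsv",
    "read_snapshot_tsv",
]

_VALID_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])
_ALLELE_RE = re.compile(r"^[ACGTN]+$")

#: Chromosome sort order used for deterministic output.
_CHROM_ORDER = {c: i for i, c in enumerate([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])}


class SnapshotFormatError(ValueError):
    """Raised when an input file violates the expected ClinVar VCF dialect."""


@dataclass(frozen=True, slots=True)
class VariantKey:
    """Exact-match variant identity: (chrom, pos, ref, alt), 1-based GRCh37.

    Two keys are equal iff all four fields are equal; no normalization happens
    at comparison time.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chrom not in _VALID_CHROMS:
            raise ValueError(f"invalid chromosome {self.chrom!r}")
        if not isinstance(self.pos, int) or self.pos < 1:
            raise ValueError(f"position must be a positive integer, got {self.pos!r}")
        if not _ALLELE_RE.match(self.ref):
            raise ValueError(f"invalid ref allele {self.ref!r}")
        if not _ALLELE_RE.match(self.alt):
            raise ValueError(f"invalid alt allele {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, both {self.ref!r}")

    def sort_key(self) -> tuple[int, int, str, str]:
        return (_CHROM_ORDER[self.chrom], self.pos, self.ref, self.alt)


@dataclass(frozen=True, slots=True)
class ClinVarRecord:
    """One snapshot entry: a variant key plus its verbatim annotation strings."""

    key: VariantKey
    genes: tuple[str, ...]
    clnsig_raw: str
    revstat_raw: str
    origin_raw: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene symbols in {self.genes!r}")

    def panel_genes(self, panel: frozenset[str]) -> tuple[str, ...]:
        """Genes of this record that belong to ``panel`` (attribution order kept)."""
        return tuple(g for g in self.genes if g in panel)


@dataclass(slots=True)
class SnapshotTable:
    """A dated, immutable pull of ClinVar restricted to a gene panel."""

    label: str
    records: dict[VariantKey, ClinVarRecord]
    gene_panel: frozenset[str]

    def __post_init__(self) -> None:
        for key, rec in self.records.items():
            if rec.key != key:
                raise ValueError(f"record keyed {key} carries key {rec.key}")
            if not set(rec.genes) & self.gene_panel:
                raise ValueError(
                    f"record {key} has no gene in the panel: {rec.genes!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnapshotTable):
            return NotImplemented
        return (
            self.label == other.label
            and self.gene_panel == other.gene_panel
            and self.records == other.records
        )

    def sorted_records(self) -> list[ClinVarRecord]:
        return [self.records[k] for k in sorted(self.records, key=VariantKey.sort_key)]


def _open_text(path: Path) -> IO[str]:
    # Sniff gzip by magic bytes so .vcf/.vcf.gz naming does not matter.
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _parse_info(info: str) -> dict[str, str]:
    """Split a VCF INFO field into verbatim ``key -> value`` substrings."""
    out: dict[str, str] = {}
    if info == "." or info == "":
        return out
    for item in info.split(";"):
        if not item:
            continue
        key, sep, value = item.partition("=")
        out[key] = value if sep else ""
    return out


def _split_geneinfo(geneinfo: str) -> tuple[str, ...]:
    """``"BRCA1:672|NBR2:10230"`` -> ``("BRCA1", "NBR2")``, de-duplicated."""
    genes: list[str] = []
    for entry in geneinfo.split("|"):
        symbol = entry.split(":", 1)[0].strip()
        if symbol and symbol not in genes:
            genes.append(symbol)
    return tuple(genes)


def _origin_has_germline_bit(origin_raw: str | None) -> bool:
    if origin_raw is None:
        return False
    try:
        return bool(int(origin_raw) & 1)
    except ValueError:
        return False


def read_clinvar_vcf(
    path: str | Path,
    gene_panel: Iterable[str],
    label: str | None = None,
    germline_origin_only: bool = False,
) -> SnapshotTable:
    """Read a ClinVar VCF snapshot and restrict it to ``gene_panel``.

    A data line is retained iff its ALT is a single concrete allele and at
    least one GENEINFO gene symbol is in the panel.  Lines with symbolic or
    missing ALT are dropped; multi-allelic lines are a fatal error because the
    ClinVar VCF emits one variation per line and a violation signals a wrong
    input file.  CLNSIG/CLNREVSTAT are stored verbatim (empty string when the
    INFO key is absent).  Leading ``chr`` prefixes are stripped from chromosome
    names on ingest.

    Parameters
    ----------
    path
        Plain or gzip VCF file.
    gene_panel
        Gene symbols defining the restriction.
    label
        Snapshot identifier; defaults to the file stem.
    germline_origin_only
        Off by default (the ClinVar VCF is a germline-oriented aggregate and
        no origin filter is implied by the default reading).  When on, only
        records whose ORIGIN bitmask includes the germline bit (0x1) are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"snapshot VCF not found: {path}")
    panel = frozenset(g.upper() for g in gene_panel)
    if not panel:
        raise ValueError("gene_panel must be non-empty")

    records: dict[VariantKey, ClinVarRecord] = {}
    saw_header = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("##"):
                if lineno == 1 and not line.startswith("##fileformat=VCF"):
                    raise SnapshotFormatError(
                        f"{path}: first line is not a VCF fileformat declaration"
                    )
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not saw_header:
                raise SnapshotFormatError(
                    f"{path}:{lineno}: data line before #CHROM header"
                )
            fields = line.split("\t")
            if len(fields) < 8:
                raise SnapshotFormatError(
                    f"{path}:{lineno}: expected >=8 tab-separated columns, got {len(fields)}"
                )
            chrom, pos_s, _vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            info = fields[7]
            if "," in alt:
                raise SnapshotFormatError(
                    f"{path}:{lineno}: multi-allelic ALT {alt!r}; "
                    "ClinVar emits one variation per line — wrong input file?"
                )
            if alt == "." or alt.startswith("<") or "[" in alt or "]" in alt or alt == "*":
                continue  # symbolic / missing ALT: not a short variant
            if chrom.startswith("chr"):
                chrom = chrom[3:]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise SnapshotFormatError(f"{path}:{lineno}: malformed POS {pos_s!r}") from exc
            info_map = _parse_info(info)
            genes = _split_geneinfo(info_map.get("GENEINFO", ""))
            if not set(genes) & panel:
                continue
            if germline_origin_only and not _origin_has_germline_bit(info_map.get("ORIGIN")):
                continue
            try:
                key = VariantKey(chrom=chrom, pos=pos, ref=ref.upper(), alt=alt.upper())
            except ValueError as exc:
                raise SnapshotFormatError(f"{path}:{lineno}: {exc}") from exc
            if key in records:
                # Aggregate file should be unique per variation; keep the first
                # occurrence so re-reads stay deterministic.
                continue
            records[key] = ClinVarRecord(
                key=key,
                genes=genes,
                clnsig_raw=info_map.get("CLNSIG", ""),
                revstat_raw=info_map.get("CLNREVSTAT", ""),
                origin_raw=info_map.get("ORIGIN"),
            )

    return SnapshotTable(label=label or path.stem, records=records, gene_panel=panel)


_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "genes", "clnsig_raw", "revstat_raw", "origin_raw"]


def write_snapshot_tsv(snapshot: SnapshotTable, path: str | Path) -> None:
    """Write the snapshot as a TSV, one row per record in key order.

    Label and panel go into leading ``#``-comment lines so the companion
    reader can round-trip the full table.
    """
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#label={snapshot.label}\n")
        fh.write(f"#gene_panel={','.join(sorted(snapshot.gene_panel))}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for rec in snapshot.sorted_records():
            fh.write(
                "\t".join(
                    [
                        rec.key.chrom,
                        str(rec.key.pos),
                        rec.key.ref,
                        rec.key.alt,
                        ",".join(rec.genes),
                        rec.clnsig_raw,
                        rec.revstat_raw,
                        rec.origin_raw if rec.origin_raw is not None else ".",
                    ]
                )
                + "\n"
            )


def read_snapshot_tsv(path: str | Path) -> SnapshotTable:
    """Companion reader for :func:`write_snapshot_tsv` (lossless round-trip)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"snapshot TSV not found: {path}")
    label = ""
    panel: frozenset[str] = frozenset()
    records: dict[VariantKey, ClinVarRecord] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header_seen = False
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#label="):
                label = line.partition("=")[2]
                continue
            if line.startswith("#gene_panel="):
                panel = frozenset(line.partition("=")[2].split(","))
                continue
            if not header_seen:
                if line.split("\t") != _TSV_COLUMNS:
                    raise SnapshotFormatError(f"{path}: unexpected TSV header {line!r}")
                header_seen = True
                continue
            if not line:
                continue
            chrom, pos, ref, alt, genes, clnsig, revstat, origin = line.split("\t")
            key = VariantKey(chrom=chrom, pos=int(pos), ref=ref, alt=alt)
            records[key] = ClinVarRecord(
                key=key,
                genes=tuple(g for g in genes.split(",") if g),
                clnsig_raw=clnsig,
                revstat_raw=revstat,
                origin_raw=None if origin == "." else origin,
            )
    return SnapshotTable(label=label, records=records, gene_panel=panel)
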