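from __future__ import annotations

from pathlib import Path

import pytest

from germline_banner.clinvar_snapshot_io import ClinVarRecord, SnapshotTable, VariantKey
from germline_banner.ppgv_caller import DEFAULT_GENE_PANEL

VCF_HEADER = (
    "##fileformat=VCFv4.1\n"
    '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">\n'
    '##INFO=<ID=CLNREVSTAT,Number=.,Type=String,Description="Review status">\n'
    '##INFO=<ID=GENEINFO,Number=1,Type=String,Description="Gene symbol:id pairs">\n'
    '##INFO=<ID=ORIGIN,Number=.,Type=String,Description="Allele origin">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def make_vcf(path: Path, data_lines: list[str]) -> Path:
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in data_lines), encoding="utf-8")
    return path


def make_record(
    chrom="17",
    pos=41244000,
    ref="A",
    alt="G",
    genes=("BRCA1",),
    clnsig="Pathogenic",
    revstat="criteria_provided,_multiple_submitters,_no_conflicts",
    origin=None,
) -> ClinVarRecord:
    return ClinVarRecord(
        key=VariantKey(chrom=chrom, pos=pos, ref=ref, alt=alt),
        genes=tuple(genes),
        clnsig_raw=clnsig,
        revstat_raw=revstat,
        origin_raw=origin,
    )


def make_snapshot(records, label="test", panel=DEFAULT_GENE_PANEL) -> SnapshotTable:
    return SnapshotTable(
        label=label, records={r.key: r for r in records}, gene_panel=frozenset(panel)
    )


@pytest.fixture
def toy_vcf(tmp_path: Path) -> Path:
    """Three data lines: BRCA1 and ATM in the panel, TP53 outside it."""
    lines = [
        "17\t41244000\t1\tA\tG\t.\t.\t"
        "CLNSIG=Pathogenic;CLNREVSTAT=reviewed_by_expert_panel;GENEINFO=BRCA1:672",
        "17\t7577000\t2\tC\tT\t.\t.\t"
        "CLNSIG=Benign;CLNREVSTAT=criteria_provided,_single_submitter;GENEINFO=TP53:7157",
        "11\t108121000\t3\tG\tA\t.\t.\t"
        "CLNSIG=Uncertain_significance;CLNREVSTAT=criteria_provided,_single_submitter;"
        "GENEINFO=ATM:472",
    ]
    return make_vcf(tmp_path / "toy.vcf", lines)
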