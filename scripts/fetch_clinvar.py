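#!/usr/bin/env python
"""Download the dated ClinVar GRCh37 archive pulls (network required).

Usage:
    python scripts/fetch_clinvar.py [--out-dir data/clinvar] [--extract-panel]

Fetches the 2022-03-13 and 2024-03-01 GRCh37 VCF archives from the NCBI
ClinVar FTP mirror.  With --extract-panel, additionally writes
panel-restricted plain-text extracts (24 banner genes only, ~25 MB total)
next to the downloads; the extracts are sufficient for
scripts/acceptance.py and the archive-reproduction acceptance test, and
being plain text they survive text-only repository snapshots.
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

REPO_ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO_ROOT / "src"))

BASE = "https://ftp.ncbi.nlm.nih.gov/pub/clinvar/vcf_GRCh37/archive_2.0"
ARCHIVES = {
    "clinvar_20220313.vcf.gz": f"{BASE}/2022/clinvar_20220313.vcf.gz",
    "clinvar_20240301.vcf.gz": f"{BASE}/2024/clinvar_20240301.vcf.gz",
}


def fetch(url: str, dest: Path) -> None:
    if dest.exists():
        print(f"already present: {dest}", file=sys.stderr)
        return
    print(f"downloading {url} -> {dest}", file=sys.stderr)
    tmp = dest.with_suffix(dest.suffix + ".part")
    urllib.request.urlretrieve(url, tmp)
    tmp.rename(dest)


def extract_panel(src: Path, dest: Path) -> None:
    from germline_banner.clinvar_snapshot_io import read_clinvar_vcf
    from germline_banner.ppgv_caller import DEFAULT_GENE_PANEL
    from germline_banner.synthetic_data import write_clinvar_vcf

    print(f"extracting banner-gene records: {src} -> {dest}", file=sys.stderr)
    snap = read_clinvar_vcf(src, DEFAULT_GENE_PANEL, label=src.stem)
    write_clinvar_vcf(snap, dest)
    print(f"  {len(snap)} records", file=sys.stderr)


def main(argv: list[str] | None = None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=REPO_ROOT / "data" / "clinvar")
    parser.add_argument("--extract-panel", action="store_true",
                        help="also write plain-text panel-restricted extracts")
    args = parser.parse_args(argv)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    for name, url in ARCHIVES.items():
        fetch(url, args.out_dir / name)
    if args.extract_panel:
        for name in ARCHIVES:
            src = args.out_dir / name
            dest = args.out_dir / name.replace(".vcf.gz", ".panel.vcf")
            extract_panel(src, dest)
            # keep only the text extract in the repo-visible directory
            print(f"note: {src} is compressed; remove it if a text-only tree "
                  "is required (the .panel.vcf extract suffices)", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
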