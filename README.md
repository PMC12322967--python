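# germline-banner

Classification of tumor-detected potential pathogenic germline variants
(PPGVs) against ClinVar evidence, and analysis of how the evolution of the
ClinVar database between two dated snapshots changes that classification —
including ancestry-disparity statistics.

The package implements:

- **ClinVar snapshot I/O** (`clinvar_snapshot_io`): reads a ClinVar-dialect
  VCF (plain or gzip), restricts it to a gene panel, and keeps the `CLNSIG` /
  `CLNREVSTAT` strings verbatim for auditability.
- **Evidence classification** (`evidence_classification`): maps aggregate
  significance + review status to P/LP, B/LB, or VUS. P/LP and B/LB require
  support by multiple submitters without conflicts or by an expert panel;
  everything else (including single-submitter pathogenic assertions) is VUS.
- **PPGV calling** (`ppgv_caller`): a tumor call is a PPGV iff it is (i) in
  the 24-gene susceptibility panel, (ii) at/above the specimen VAF threshold
  (tissue ≥ 10%, liquid ≥ 30%), and (iii) evidence-sufficient P/LP in the
  snapshot. Each decision carries a single filter reason.
- **Snapshot evolution** (`snapshot_evolution`): per-class and per-gene
  diffing of two snapshots, novel-variant detection, and the evidence mix of
  novel entries.
- **Cohort analysis** (`cohort_analysis`): prevalence by cancer type /
  ancestry, decomposition of ClinVar-filtered calls by reason, and
  each-vs-EUR Fisher exact tests with Benjamini–Hochberg correction.
- **Synthetic data** (`synthetic_data`): seeded generators for paired
  ClinVar-like snapshots (with configurable growth and review-status
  upgrades) and tumor cohorts with known per-ancestry carrier rate and
  ClinVar-representation probability, so the whole pipeline is testable
  offline with ground truth.

## CLI

```sh
banner simulate --seed 1 --out sim/              # built-in demo scenario
banner simulate --scenario scenario.yaml --out sim/
banner classify-snapshot --snapshot sim/sim2022.vcf --out classified.tsv
banner diff --snapshot-a sim/sim2022.vcf --snapshot-b sim/sim2024.vcf --out-dir diff/
banner call-ppgv --snapshot sim/sim2024.vcf --calls sim/calls.tsv \
       --samples sim/samples.tsv --out ppgv/
banner cohort-report --decisions ppgv/decisions.tsv --samples sim/samples.tsv \
       --out-dir report/
banner run-all --snapshot-a sim/sim2022.vcf --snapshot-b sim/sim2024.vcf \
       --calls sim/calls.tsv --samples sim/samples.tsv --out full/
```

`run-all` executes classify → diff → PPGV calling under both snapshots →
cohort report, writing TSV/JSON artifacts plus a run manifest. All outputs
are plain text; percent-of-baseline and percentage-point changes are reported
under distinct field names.

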