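# pgxburden

Population-stratified functional-variant burden scoring for drug-related
genes. From an annotated multi-population exome variant file (VCF with
`AC_<POP>`/`AN_<POP>` INFO fields and VEP-style `CSQ` annotations) and a
drug→target relation table, the package computes:

- **CAP** (cumulative allele probability) per gene and population — the
  probability that a diploid individual carries at least one functional
  variant allele, `1 − ∏ (1 − AF)²` under Hardy–Weinberg and cross-locus
  independence;
- **DRP** (drug risk probability) per drug — the same aggregated over a
  drug's pharmacological target genes;
- loss-of-function-only and rare/common decompositions of both;
- pairwise and population-specific mean risk differences, population-unique
  variant fractions, and threshold summaries;
- an OLS regression of DRP on target count with one-sided outlier flagging.

A synthetic-cohort generator (`pgxburden.synthetic_data`) emits the same VCF
dialect with a full analytic ground-truth table, so every stage is testable
offline.

## Layout

| module | role |
| --- | --- |
| `variant_ingest` | VCF parsing, multi-allelic splitting, indel normalization, per-population allele frequencies |
| `cohort_filters` | locus-coverage / synonymous / duplicate / AF-cap exclusion cascade with funnel reporting |
| `functional_classes` | LoF (high-confidence flags) and SIFT+PolyPhen consensus classification; CADD/effect-score concordance |
| `drug_gene_catalog` | drug→target extraction, ATC oncology tagging, gene panels, drug-name mapping |
| `risk_scores` | CAP, CAP_LoF, DRP, rare/common decompositions, variants per residue |
| `population_analysis` | risk differences, mean pairwise RD, uniqueness, threshold counts |
| `association_stats` | OLS fit of DRP vs target count, residual flagging |
| `synthetic_data` | cohort/catalog/score simulators with analytic truth tables |
| `cli` | pipeline orchestration, manifests, `pgxburden` command |

## CLI

```bash
# generate a small synthetic cohort + catalog
pgxburden simulate --out-dir sim --seed 1 --n-genes 50 --n-drugs 20 --scale 10

# run the full pipeline from a YAML config
pgxburden run-all --config config.yaml
```

A minimal `config.yaml`:

```yaml
variant_file: sim/cohort.vcf
catalog_file: sim/relations.tsv
gene_lengths_file: sim/gene_lengths.tsv
output_dir: out
filter:
  min_global_an: 6080   # ceil(0.5 * 2N) for the simulated cohort
```

The run writes `gene_scores.tsv`, `drug_scores.tsv`, `population_rd.tsv`,
`population_summary.tsv`, `uniqueness.tsv`, `regression_report.tsv`, and a
`manifest.json` with config hash, input checksums, and per-stage funnel
counts.

## Assumptions worth knowing

- The `(1 − AF)²` genotype term assumes Hardy–Weinberg equilibrium at each
  locus and independence across loci; all loci are treated as diploid
  (a warning is logged for X/Y).
- Only high-confidence LoF flags count as loss-of-function by default
  (configurable).
- A variant is damaging if *any* transcript satisfies the SIFT+PolyPhen
  consensus (worst-consequence policy, configurable to canonical-only).
- The effect-score "damaging" call used in concordance checks defaults to
  score < 0 (deleterious relative to wild type); this is a package default,
  not a published threshold.
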