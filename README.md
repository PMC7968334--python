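# raredx

Downstream interpretation toolkit for rare-disease whole-genome sequencing.
It implements the bespoke post-variant-calling stages of a clinical WGS
workflow — everything after the aligner/callers have produced VCFs:

- **core_io** — domain types and readers/writers (VCF v4.2 via cyvcf2, PED,
  BED masks, TSV panels), multi-allelic splitting and allele normalization.
- **inheritance** — per-variant/per-family deduction of compatible Mendelian
  models (AD, AR, X-linked, each with de novo sub-models, plus MT), mosaic
  flagging and compound-heterozygote pairing from parental genotypes.
- **ranking** — configurable weighted-sum rank model (per-category
  first-match rules, integer points, validated frequency monotonicity) with
  deterministic case-level ordering.
- **obsdb** — local observation database counting observing families
  (one individual per family) for cohort-specific rarity and artifact
  down-prioritization.
- **panels** — precompiled, HPO-generated and merged in-silico gene panels,
  applied as post-hoc filters.
- **triage** — secondary-verification waiver decisions: a reported variant
  skips orthogonal confirmation only when it is an SNV with depth >= 20,
  genotype quality at the caller maximum (99), caller-PASS, outside
  segmental duplications and good on visual inspection.
- **qc_str_upd** — trio relationship confirmation (Mendelian-error rate),
  SNP-fingerprint concordance, STR expansion classification against a locus
  catalog, and trio-based UPD screening from opposite-homozygote sites.
- **coverage** — transcript completeness (mean coverage, fraction of bases
  at depth cutoffs, fully-covered transcript counts) from BED4 depth tracks.
- **cohort_report** — diagnostic yield, inheritance distribution and gene
  recurrence aggregated over case results, with all percentages carrying
  their raw counts.
- **synth** — deterministic synthetic fixtures: trios with planted
  inheritance models (including compound-het pairs and a maternal-UPD
  chromosome mode), triage sets with a requested criterion composition, and
  case tables realizing given marginals.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis) and exhaustive oracle
checks: inheritance deduction is compared against an independent brute-force
enumerator over all trio genotype configurations, coverage against a
per-base expansion, triage against its full 2^6 criterion truth table.

## CLI

A single `raredx` entry point wires the modules into the interpretation
flow:

```sh
# generate a synthetic trio with a planted de novo dominant variant
raredx synth --seed 7 --plant AD_dn:SCN1A \
    --out-vcf trio.vcf --out-ped trio.ped --out-truth truth.tsv

# full flow: normalize -> local-obs annotate -> panel filter -> inheritance
# -> score -> rank
raredx annotate-rank --vcf trio.vcf --ped trio.ped --panel panel.tsv \
    --out-vcf scored.vcf --out-tsv ranked.tsv --manifest run.json

# verification triage per reported variant
raredx triage --vcf scored.vcf --sample FAM1_child \
    --segdup-bed segdup.bed --out triage.tsv

# other groups: obsdb load|dump, panel build-hpo|merge,
# qc trio|upd|str, coverage, report, reanalyze
```

Scored VCFs carry `RankScore`, `RankResult` and `GeneticModels` INFO keys.
The shipped default rank model (`src/raredx/data/rank_model_default.ini`)
uses implementer-chosen, hand-auditable weights; supply your own config for
production use.

## Known limitations

- Allele normalization trims shared suffix/prefix only; reference-guided
  left-alignment would need a FASTA and is out of scope.
- The UPD statistic and its thresholds (>= 10 signal sites, >= 0.9 signal
  fraction, ROH fraction >= 0.8 for isodisomy) are this toolkit's own
  simple design, not a reimplementation of any published caller.
- HPO panels are built by term→gene union without ontology-descendant
  closure.
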