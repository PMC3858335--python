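# cypscope

A toolkit for analysing polymorphic cytochrome P450 (CYP) enzymes:

- **`cypscope.textmine_relations`** — dictionary-based entity recognition over
  abstracts and distance-rule scoring of (CYP, ethnicity, frequency, effect)
  relation candidates, with deduplication, validation-state tracking and TSV
  export. A candidate with CYP–ethnicity token distance ≤ 7 and
  frequency–CYP distance ≤ 6 (not negated) scores exactly 100; larger
  distances decay linearly (10 points per excess token by default) and
  negation halves the score.
- **`cypscope.allele_catalog`** — a curated Caucasian star-allele frequency
  catalog (34 alleles, shipped as `data/table1_caucasian.tsv`), the ≥1%
  pharmacogenetic-polymorphism filter, per-CYP summaries, lookups and a
  generic count/coverage summarizer. Source discrepancies are documented in
  `data/ERRATA.md`.
- **`cypscope.popfreq`** — AC/AN allele frequencies from VCF genotypes
  (multi-allelic splitting, missing-genotype handling, annotation-driven
  consequence classes), the non-synonymous ≥1% filter, cohort-level
  star-allele presence calls and known/novel partitioning. A pre-computed
  72-SNP frequency table over 24 CYPs ships as `data/table2_1000g.tsv`.
- **`cypscope.expression_map`** — probe→gene aggregation, per-gene relative
  expression z-scores across tissues, and fold-threshold body-map calls
  (default two-fold; three-fold available).
- **`cypscope.synthetic_data`** — seed-deterministic generators (abstract
  corpora with planted relations, Hardy–Weinberg VCFs with known allele
  frequencies, log-normal expression matrices with planted fold effects),
  each returning a ground-truth ledger for recovery testing.

## CLI

```sh
# relation mining (packaged lexicon by default; YAML config supported,
# CLI flags override config keys)
cypscope mine --corpus corpus.tsv --min-score 100 --out hits.tsv

# star-allele catalog queries
cypscope catalog --summary
cypscope catalog --lookup 2D6 '*4'
cypscope catalog --filter-threshold 20 --summary

# allele frequencies from a VCF, with optional star-allele definitions
cypscope popfreq --vcf cohort.vcf --definitions defs.tsv --threshold 1.0 \
    --summary --out freqs.tsv

# expression body map
cypscope express --matrix matrix.tsv --probe-map probes.tsv \
    --fold-threshold 2.0 --out-prefix out

# synthetic inputs with ground-truth ledgers
cypscope simulate abstracts --n-docs 200 --n-planted 100 --seed 1 \
    --out corpus.tsv --truth truth.tsv
cypscope simulate vcf --n-samples 1000 --spec 2A6:NON_SYNONYMOUS:0.05 \
    --seed 1 --out sim.vcf --truth truth.tsv
cypscope simulate expression --plant G05:T10:6.0 --seed 1 \
    --out-prefix expr --truth truth.tsv
```

Corpus format: TSV with columns `doc_id`, `title`, `abstract`, or a
directory of `<doc_id>.txt` files. Lexicon format: TSV with
`entity_class` (CYP/ETHNICITY/FREQUENCY/EFFECT/NEGATION), `surface_form`,
`canonical_id`.

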