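# lnckit

A toolkit for long-noncoding-RNA discovery and integration on unreplicated,
pooled stage libraries:

- **filter_cascade** — seven-step candidate-lncRNA screen (sense-exon
  overlap, length ≥ 200 bp, ≥ 2 exons, read coverage ≥ 0.8, FPKM ≥ 0.1,
  six-frame ORF ≤ 100 aa, protein-evidence exclusion list, 2-kb
  scaffold-end margin, optional poly(A) gate) with first-failing-rule
  attribution and per-step removal counts.
- **positional_classifier** — assigns each retained lncRNA exactly one of
  five classes (sense / antisense / intronic / bidirectional / intergenic)
  against a coding annotation, and finds adjacent protein-coding genes
  (apcGenes) within an inclusive 10-kb window on each side.
- **duplex_and_precursor** — parameterized complementarity alignment for
  antisense lncRNA–mRNA duplexes (GC +3, AT +2, G·U wobble +1, affine
  gaps) and miRNA hairpin-precursor matching (hit iff identity ≥ 0.90 and
  hairpin coverage > 0.90).
- **diff_expression** — exact conditional binomial test for count pairs
  from unreplicated libraries, Benjamini–Hochberg correction per contrast,
  calls at q ≤ 0.05 and |log2FC| ≥ 1 (both inclusive).
- **enrichment** — hypergeometric term enrichment with BH q-values.
- **cerna_network** — typed lncRNA–miRNA–mRNA graph (strict read-count
  > 10 screen, link requirement, DE requirement) and miRNA hub scoring by
  bridged (lncRNA, mRNA) pairs.
- **synthetic_data** — deterministic generator for a fully planted test
  dataset (annotation, sequences, expression, hairpins, targets, terms)
  with machine-readable ground truth.
- **annotation_io** — GTF/FASTA/BED/TSV parsing and the shared genomic
  data model (0-based half-open coordinates internally).

## CLI

Everything is exposed through one entry point:

```sh
# generate a synthetic dataset with planted ground truth
lnckit simulate --seed 1 --out data/

# run the full pipeline
lnckit run-all \
    --gtf data/annotation.gtf --scaffolds data/scaffolds.tsv \
    --fasta data/transcripts.fa --hairpins data/hairpins.fa \
    --expr data/expression.tsv --evidence data/evidence.tsv \
    --targets data/targets.tsv --terms data/terms.tsv \
    --out run/
```

`run/manifest.json` records per-stage counts, file hashes and the full
threshold configuration; reruns on identical inputs are byte-identical.
Individual stages are available as `filter`, `classify`, `de`,
`precursor` and `enrich` subcommands and write the same files as
`run-all`.  Thresholds can be overridden with a YAML file via `--config`
(unknown keys are rejected).

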