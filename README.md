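# beprofiler

Toolkit for profiling base-editing outcomes on combinatorial
sequence-context substrate libraries, plus directed-evolution bookkeeping.

Modules:

- **library_design** — enumerate UMI-barcoded context libraries (target base ×
  protospacer position × 5′/3′ flank), materialize reference amplicons, write
  FASTA + TSV manifest. Protospacer positions are 1-based with the PAM at
  21–23.
- **synthetic_reads** — simulate FASTQ reads from a library with known
  per-member conversion rates (C→T / A→G), optional cross-conversions,
  sequencing error and an indel path; emits a ground-truth table.
- **edit_caller** — UMI demultiplexing (nearest barcode within a mismatch
  tolerance), gapless per-position substitution calling with indel exclusion
  and quality masking, replicate averaging; long-format edits TSV.
- **profile_stats** — per-position average profiles, editing window
  (positions ≥ 20% of the peak average), flank-context matrices, and the
  C-over-A selectivity ratio (geometric mean over positions, denominators
  floored at the 0.1% detection limit → lower bounds).
- **context_logo** — editing-weighted flank-base frequencies over the window
  and Kullback–Leibler letter heights `f·log2(f/0.25)`.
- **selection_metrics** — plaque titers (plaques × dilution × 100), fold
  enrichment, and cumulative fold-dilution across discrete passages and
  continuous washout segments, accumulated in log10 space.
- **pipeline** / **cli** — one-command end-to-end run with a checksummed
  report.

## CLI

```sh
beprofiler design --targets AC --positions 1-14 --umi-len 10 --seed 1 -o lib/
beprofiler simulate --library lib/library_manifest.tsv --p-target 0.9 \
    --error 0.001 --depth 1000 --reps 3 --seed 1 -o sim/
beprofiler call --reads sim/reads_rep1.fastq --library lib/library_manifest.tsv \
    --qmin 20 --min-reads 100 -o call/
beprofiler stats --edits call/edits.tsv --library lib/library_manifest.tsv \
    --window-threshold 0.2 --selectivity-positions 4-8 --lod 0.1 -o stats/
beprofiler logo --edits call/edits.tsv --library lib/library_manifest.tsv \
    --window 4-8 --conversion C2T -o logo/
beprofiler dilution --campaign campaign.yaml
beprofiler run --config run.yaml      # design → simulate → call → stats → logo
```

A run config YAML mirrors `beprofiler.pipeline.RunConfig`; see
`RunConfig().to_yaml(path)` for a template.

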