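# proximatome

Quantitative analysis of proximity-labeling (BioID/TurboID) interactome
experiments, for proteomics groups who have spectral-count tables in hand
and want the downstream statistics to be explicit, reproducible and tested:

* **Enrichment** of bait over control purifications from label-free
  spectral counts: `FC = (mean bait SpC + α)/(mean control SpC + α)` with a
  choice of confidence backends (pass-through of an upstream SAINT-style
  export, an exact binomial count-split test, or label permutation),
  Benjamini–Hochberg FDR, and the standard volcano selection FC > 2,
  FDR < 0.1 (both strict).
* **Time-course classification**: proteins enriched at both a short and a
  long labeling duration get the FC-variation ratio `R = FC_late/FC_early`;
  `R < 0.5` marks stable interactors whose relative enrichment decays
  (group 1), `R ≥ 0.5` marks stable/increasing enrichment — the signature
  of high-flux substrates such as mitochondrial precursors (group 2).
* **Length-normalized abundance** `A = mean SpC / L`, z-scoring (n−1 sd)
  and paired z-scale comparison of two proteomes.
* **Peptide coverage vs MTS**: interval merging and overlap with annotated
  N-terminal mitochondrial targeting sequences, to distinguish matured from
  precursor protein pools.
* **Set integration**: APEX-seq-style mRNA table filtering (FDR < 0.1,
  log2FC > 0), overlap statistics with explicit denominators, annotation
  tagging (Mitocarta membership, MTS, mito-encoded).
* **qPCR statistics**: `2^−ΔΔCT` relative expression, RIP/fraction
  `% of input` with input-dilution correction, and mRNA decay half-life
  fitting.
* A **synthetic-data generator** with planted ground truth (negative-
  binomial counts, three protein classes, two labeling durations) so every
  stage runs and is testable with no external data.

## Worked example

Generate a synthetic two-timepoint experiment (300 proteins, 3 bait + 3
control replicates per timepoint) and run the full pipeline:

```bash
proximatome simulate timecourse --seed 7 --n-proteins 300 --outdir fixtures
cat > pipeline.yaml <<'YAML'
counts: fixtures/counts_early.tsv
design: fixtures/design_early.tsv
late_counts: fixtures/counts_late.tsv
late_design: fixtures/design_late.tsv
annotations: fixtures/annotations.tsv
backend: binomial
outdir: out
YAML
proximatome run --config pipeline.yaml
```

which prints (abridged):

```json
{
  "n_enriched_early": 62,
  "n_enriched_late": 43,
  "enriched_annotation": {"n_mitochondrial": 28, "n_total": 62, "n_with_mts": 28},
  "timecourse": {
    "groups": {
      "group1": {"size": 7,  "n_annotated_true": 1,  "share_percent": 3.7},
      "group2": {"size": 32, "n_annotated_true": 26, "share_percent": 96.3}
    },
    "n_classified": 39, "n_only_early": 23, "n_only_late": 4
  }
}
```

Reading: 62 proteins pass FC > 2, FDR < 0.1 at the short labeling (28 of
them mitochondrial), 43 at the long one; 39 proteins are enriched at both
timepoints and get classified, and 96.3% of the classified mitochondrial
proteins fall in group 2 — the high-flux substrate group — while group 1
holds the stable interactors. Proteins enriched at only one timepoint (23 +
4) are listed, not classified. Per-protein tables land in `out/`
(`enrichment_early.tsv`, `enrichment_late.tsv`, `groups.tsv`), with a
parameter echo and per-stage record counts in `out/run.log`.

The same stages are available individually (`proximatome enrich`,
`timecourse`, `compare-proteomes`, `coverage`, `integrate`, `qpcr`,
`simulate`) and as plain library functions
(`proximatome.enrichment.build_records`, `proximatome.timecourse.classify_groups`, ...).

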