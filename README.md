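# regcircuit

Comparative gene-regulatory analysis of two epithelial cell states against a
reference state, as a reusable, tested pipeline:

- **CRE catalogue** — merge the top-N accessibility peaks of each cell state
  by summit proximity, quantify ATAC/H3K4me3/H3K27ac/H3K27me3 signal in
  mark-specific windows (200 bp / 2 kb / 2 kb / 5 kb), normalize
  (log10 + quantile), and classify each CRE's epigenetic state between the
  two cell states: a negative-binomial Wald test for the count marks
  (ATAC, H3K27ac) and a two-step activity/variability selection for the
  threshold marks (H3K4me3, H3K27me3).
- **Gene linking** — promoter links (closest TSS within 20 kb) and enhancer
  aggregates (logistic distance-weighted sums over all CREs within 100 kb of
  a TSS, half weight at 50 kb, full weight inside 2 kb).
- **Binding networks & influence** — TF-to-gene binding scores from motif
  presence x CRE activity x distance weight; reference-anchored differential
  networks; per-TF influence scaled 0-1; shared vs. cell-type-specific TF
  classification (shared = influence > 0.5 in both reference comparisons);
  TF-hierarchy edge labels from delta binding scores.
- **Disease enrichment** — per-gene distance-weighted TF binding scores, a
  one-sided Mann-Whitney U test (exact and tie-aware up to n = 50) and a
  nearest-TSS Fisher exact test, BH FDR at 0.1, top-5 bound loci.
- **Expression stats** — gene filters (sex chromosomes, < 10 counts),
  NB Wald differential expression (padj <= 0.01, |log2FC| >= 0.58), batch
  removal for visualization, preranked GSEA with a permutation null.
- **Synthetic data** — a miniature two-state (+reference) genome with planted
  differential CREs, shared/state-specific TF programs, motif hits, and
  excess TF binding near a disease gene list, with full ground truth, so
  every stage is testable without external downloads.

## Run the pipeline

```bash
regcircuit init-config --out cfg          # write default YAML configs
regcircuit all --config cfg/pipeline.yaml --sim-config cfg/simulation.yaml \
    --seed 1 --out out
```

Stages can also be run individually in dependency order
(`simulate`, `quantify`, `differential`, `link`, `de`, `grn`, `hierarchy`,
`disease`, `gsea`, `motif`); a stage whose prerequisites are missing fails
with a message naming the stage to run first. Every stage appends a log entry
(config hash, seed, input checksums) to `out/run_log.jsonl`, and reruns with
the same config and seed are byte-identical.

All interval arithmetic is 0-based half-open (BED convention). Formats:
narrowPeak, BED6, TSV matrices (header = sample ids, first column = feature
id), plain-text gene lists, JSON.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` contains the acceptance criteria, including the
simulation-based planted-effect recovery suites (20 seeds each) and the
exact-test oracles (Mann-Whitney vs. exhaustive enumeration, Fisher vs. the
closed-form hypergeometric tail).

## Notes on fidelity

- The external DE package used in the original workflow is replaced by a
  bespoke NB Wald test (median-of-ratios size factors, trend-shrunk
  method-of-moments dispersions, t reference with simulation-calibrated
  effective df). Exact equality with that package is not claimed; calibration
  and power are established by simulation in the test suite.
- The pre-trained TF binding models of the upstream network tool are replaced
  by a transparent motif x activity x distance proxy with the same
  interfaces; the comparison design on top (reference anchoring, shared-TF
  rule, delta-binding hierarchy) is implemented as specified.
- The distance-weight curve is a logistic decay anchored at w(50 kb) = 0.5
  with a 2 kb full-weight promoter radius, fully configurable; a 50 kb
  enhancer window variant is available via config.
- The differential-CRE percentage uses union-over-marks semantics.
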