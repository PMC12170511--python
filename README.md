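# hexniche

Immune-niche analysis of Visium-style spatial transcriptomics: who is near
the immune cells, how the neighborhood responds, and what sequencing depth
does to the answer.

Spatial transcriptomics of hepatocellular carcinoma (HCC) shows immune
cell-enriched capture spots scattered through both tumor and adjacent
benign liver.  The cells *next to* those spots remodel their expression —
broadly in tumor, narrowly in benign tissue — and much of that signal
disappears when the library is sequenced at ordinary depth.  `hexniche`
implements this analysis as a tested, reusable pipeline for anyone with a
spot-by-gene count matrix, spot positions and a region annotation:

- **Immune-spot calling** — mean log-CP10K expression over a 23-gene
  marker panel (Kupffer, T, B/plasma, NK lineages); spots scoring above a
  threshold (default 0.9, strict) are immune cell-enriched.
- **Hex-niche classification** — non-immune spots are `adjacent` when they
  touch an immune spot in the Visium six-neighbor contact ring
  (offsets (0, ±2), (±1, ±1) in array coordinates), else `away`,
  stratified by tumor/benign region.
- **Differential expression** — Wilcoxon rank-sum (tie-corrected normal
  approximation; exact permutation tail for small samples) with
  Benjamini–Hochberg correction and Seurat-convention fold changes, for
  the three contrasts tumor-adjacent/away, benign-adjacent/away,
  tumor-adjacent/benign-adjacent; results screened against the top-3,000
  highly variable genes.
- **Depth comparison** — binomial thinning to emulate standard depth from
  a deep run, per-gene detection deltas ("% spot detection"), a global
  two-sample Kolmogorov–Smirnov test, and DE-set overlap (Venn) erosion.
- **Compositional PERMANOVA** — centered-log-ratio transform of myeloid
  composition tables and a sequential two-factor permutational MANOVA
  (depth × region), matching vegan's `adonis2` conventions.
- **Synthetic data** — a negative-binomial generator that plants immune
  spots, adjacency-response gene programs and depth regimes with known
  ground truth, used throughout the test suite.

The statistical primitives (rank-sum, BH, KS, PERMANOVA) are implemented
from their definitions and validated against independent oracles —
exhaustive permutation enumeration, brute-force formulas, and R
`vegan::adonis2` — in the test suite.

## Worked example

Simulate the default two-slide dataset (6,272 spots, 5,000 genes, 289
planted immune spots), analyze it at deep depth and after 35× thinning,
and print the report:

```python
from hexniche import PipelineConfig, SyntheticConfig, run_pipeline

cfg = PipelineConfig(outdir="out", simulate=SyntheticConfig(seed=1))
report = run_pipeline(cfg)
print(open("out/report.txt").read())
```

```
hexniche report
================

analyzed spots: 6272 (tumor 5488, benign 784)
[deep] immune 289, adjacent 1387, away 4596
    tumor_adjacent_vs_away: 200 significant (195 also highly variable)
    benign_adjacent_vs_away: 67 significant (46 also highly variable)
    tumor_adjacent_vs_benign_adjacent: 373 significant (338 also highly variable)
[standard] immune 132, adjacent 703, away 5437
    tumor_adjacent_vs_away: 146 significant (98 also highly variable)
    benign_adjacent_vs_away: 10 significant (6 also highly variable)
    tumor_adjacent_vs_benign_adjacent: 140 significant (90 also highly variable)
detection: 5000/5000 genes (100%) higher at deep depth; KS D = 0.757
PERMANOVA depth: p = 0.001
PERMANOVA region: p = 0.001
PERMANOVA depth x region: p = 0.425
```

Reading this: all 289 planted immune spots were recovered at deep depth
(their 1,387-spot contact ring splits into 1,079 tumor and 308 benign
spots); the tumor neighborhood shows three times the benign response
(200 vs 67 planted response genes, all recovered); thinning to standard
depth halves the immune-spot count, erodes every DE contrast, and strictly
reduces detection for essentially all genes; and both depth and region
shift the simulated myeloid composition of the immune spots.

The same stages are available as subcommands of the `hexniche` CLI
(`simulate`, `call-niches`, `de`, `thin`, `depth-compare`, `permanova`,
`run-all`), and the library functions accept standard formats: Matrix
Market count triplets, `tissue_positions.csv`, and plain CSV region/label
tables.

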