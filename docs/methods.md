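# Methods

`hexniche` analyzes Visium-style spatial transcriptomics of tumors with
infiltrating immune cells.  Its question is the one a spatial immunologist
asks of a hepatocellular-carcinoma (HCC) section: where are the immune
cell-enriched capture spots, how does the transcriptome of the *neighboring*
tissue respond to them, does that response differ between malignant and
benign regions, and how much of all this survives at ordinary sequencing
depth?  The package bundles a calibrated synthetic-data generator so every
statistical claim can be validated against known ground truth.

## Spatial substrate

Visium spots lie on a hexagonal lattice indexed by `(array_row, array_col)`
with the convention that the two indices share parity; a spot's six contacts
sit at offsets (0, ±2), (±1, ±1).  "Adjacent to immune cells" is formalized
as membership in this six-neighbor contact ring; no second-ring option is
offered.  Spots flagged out-of-tissue are retained in files but excluded
from every analysis.

## Immune-spot calling

Counts are normalized as log-CP10K, `ln(1 + c · 10⁴ / library size)` — a
deterministic transform chosen so that every downstream number is
reproducible from first principles (regularized negative-binomial
normalizations of the SCT family involve fitted regularization that is not
reproducible without the fitting code).  The immune score of a spot is the
arithmetic mean of normalized expression over a 23-gene marker panel
covering four liver immune lineages: Kupffer cells (CD68, CD163, LYZ, C1QA,
AIF1), T cells (CD3D, CD2, IL7R, TRBC2, CD69), B/plasma cells (IGKC,
JCHAIN, CD79A, CD27, CD74) and NK/other cytotoxic cells (CD4, CD8A, ITGAM,
NKG7, KLRD1, PRF1, CD7, TRDC).  A spot is immune cell-enriched when its
score strictly exceeds `score_threshold` (default 0.9).  On which
normalization scale such a threshold is best interpreted is genuinely
ambiguous across toolchains, so the threshold is a config parameter and the
log-CP10K interpretation is stated rather than assumed universal.  Marker
genes missing from a probe set shrink the score denominator instead of
counting as zeros; a coverage floor (default 50% of the panel) guards
against degenerate panels.

Non-immune spots are then `adjacent` (≥1 immune hex contact) or `away`,
stratified by tissue region (tumor / benign).  Immune spots touching other
immune spots stay immune — the three classes are exclusive with precedence
immune > adjacent.

## Differential expression

Three contrasts are run, always excluding immune spots themselves:
tumor-adjacent vs tumor-away, benign-adjacent vs benign-away, and
tumor-adjacent vs benign-adjacent.  The test is the Wilcoxon/Mann-Whitney
rank-sum on log-normalized values with average ranks, tie-corrected
variance and 0.5 continuity correction.  For small samples (≤ 20,000
enumerable group assignments, e.g. two groups of 8) the scalar API returns
the exact permutation p instead, which remains correct under arbitrary tie
structure; the genome-scale screening path always uses the normal
approximation, as is standard at spot-level sample sizes.  Effect size is
the Seurat-convention fold change, `log2[(mean(expm1(x₁)) + 1) /
(mean(expm1(x₂)) + 1)]`.  Genes must reach 10% detection in at least one
group to be tested; Benjamini–Hochberg runs over tested genes only; a gene
is reported significant when q < 0.05 and |log2FC| ≥ 0.25.  All four
thresholds are config-exposed; the defaults mirror the conventions of the
mainstream single-cell toolkits.  "Integrating" DE genes with the top-3,000
highly variable genes is implemented as intersection (the restrictive
reading); union is available behind a flag.

Highly variable genes are ranked by binned standardized dispersion:
per-gene mean and dispersion (variance/mean) of log-normalized expression,
20 equal-occupancy mean bins, z-scored dispersion within each bin, ties
broken lexicographically.  On matrices with fewer than 100 genes the bin
count drops so each bin keeps at least five genes; with two-gene bins the
within-bin z-score is exactly ±1 and the ranking would be decided by
floating-point noise.

## Depth comparison

Standard-depth data is emulated by binomial thinning of deep counts — each
count replaced by Binomial(count, rate) — so depth is the only difference
between the runs (the package also accepts a physically separate standard
run).  Thinning is distribution-correct for Poisson-mixture counts and
yields an exact nesting of detection events, so per-gene detection can only
fall.  Two summaries are reported side by side because "tested by KS" in
depth comparisons is used for either: (a) the per-gene tally of strictly
increased % spot detection at deep depth, and (b) a global two-sample
Kolmogorov–Smirnov test on the two per-gene detection-rate distributions
(exact D by ECDF merge; asymptotic p at effective size n·m/(n+m)).  Neither
is presented as the other's substitute.

## Compositional analysis

Myeloid (macrophage subtype 1–6) composition tables of immune spots are
centered-log-ratio transformed (zeros replaced by ε = 10⁻⁶ and rows
re-closed — simple multiplicative replacement) and tested with PERMANOVA on
Euclidean distances: sequential (Type I) partitioning of the Gower-centered
distance matrix into depth, region, depth×region and residual, pseudo-F per
term, and p-values from permutation of raw observations,
p = (1 + #{F* ≥ F}) / (n_perm + 1).  These choices match the default
behaviour of vegan's `adonis2`, against which the implementation is checked
on a frozen fixture.  Permuting raw observations rather than reduced-model
residuals is the simpler and more common default; with balanced designs of
this size the difference is minor.

## Synthetic data generator

The generator emulates the structure of a two-slide Visium HCC case at
desk scale.  Defaults (the study conditions):

| parameter | default | meaning |
|---|---|---|
| slides, n_rows, n_cols | 2, 56, 56 | 6,272 in-tissue spots, ≈ the 6,320 of a two-slide run |
| benign_fraction_slide1 | 0.25 | contiguous benign band on slide 1; slide 2 all tumor |
| n_subclones | 15 | contiguous tumor patches via seeded region-growing (echoing the 15 tumor expression clusters such sections show) |
| n_genes | 5,000 | gene universe; baseline weights LogNormal(0, 1.5) |
| immune_spot_fraction | 0.046 | 289 immune spots on the default grid |
| immune_benign_bias | 3.0 | sampling weight within 2 hex steps of benign tissue |
| immune_marker_lognorm_target | 1.2 | floor of per-spot marker-score targets (log-CP10K) |
| immune_marker_spread | 0.7 | mean of the Gamma(2, ·) excess above the floor |
| n_response_genes_tumor / benign | 200 / 67 | planted adjacency-response genes, 3:1 tumor:benign |
| response_log2fc | 1.0 | planted shift in spots hex-adjacent to immune spots |
| nb_dispersion | 0.3 | negative-binomial overdispersion |
| depth_deep_mean / depth_standard_mean | 20,000 / 571 | lognormal library-size targets (35:1, the deep:standard ratio of ~700K vs ~20K reads/spot, scaled down absolutely for desk-scale runtime) |

Counts are negative-binomial (Gamma–Poisson) with lognormal library sizes,
the standard overdispersed model for UMI data.  Tissue identity — grid,
ground truth, gene programs, marker fractions — is derived from the seed
alone and shared between depth regimes, so an independently simulated
standard run differs from the deep run only through sampling.  All
randomness flows from the one config seed through tagged generator streams.

Design choices worth stating explicitly:

- **Marker calibration.**  Each immune spot receives a marker-score target
  drawn as floor + Gamma(shape 2) excess, and the underlying expected
  marker count is solved numerically so that the *expectation of the
  log-CP10K score under negative-binomial sampling* equals the target
  (a plug-in rate undershoots by Jensen's inequality).  The floor—rather
  than the mean—is pinned at `immune_marker_lognorm_target` because the two
  desiderata of the emulation pull apart otherwise: near-complete recall at
  deep depth needs every spot comfortably above the 0.9 threshold, while a
  realistic, non-degenerate immune set after 35× thinning needs a
  sub-population of strongly enriched spots, as in real tissue where most
  immune spots sit far above threshold and only marginal ones vanish at
  standard depth.
- **Response genes are expressed genes.**  Planted response genes are drawn
  from genes above the 60th percentile of baseline weight.  With the
  pseudocount-damped fold-change convention, a 2× shift on a near-silent
  gene is reported at |log2FC| < 0.25 and is unrecoverable by construction,
  not by failure of the method; the response programs the generator mimics
  (acute phase, integrin, ECM) are expressed hepatic genes.  Signs are
  random, half up / half down.
- **Subclone programs** perturb 5% of eligible genes per patch by
  2^N(0, 0.4) (benign program: 8% at 2^N(0, 0.6)); markers and response
  genes are excluded from program pools so planted effects stay clean.
- **Immune spots are placed independently** (with benign-proximity bias)
  rather than in spatially contagious clusters.  Consequently the adjacent
  ring is larger (~1,400 spots) than in real sections, where immune spots
  aggregate and the ring stays in the few hundreds; tests that depend on
  ring size use the generator's own geometry, not real-tissue tallies.

What the generator does **not** emulate: histology, probe chemistry,
segmentation/doublets, spatial autocorrelation of immune spots,
between-slide batch effects, and the cluster-level substructure real HCC
shows beyond the planted patch programs.  Passing tests therefore show the
statistics recover known truth under a faithful noise model — not that
every real-data artifact is handled.

## Numerical and degenerate-input choices

- Library normalization errors out on zero-total spots, listing them.
- Strict inequalities throughout: immune calling (> threshold), detection
  increase (delta > 0).
- Rank computations run on an order-preserving integer recoding of the
  normalized values (cached per matrix); ranks and tie structure are
  identical to sorting the floats, but integer radix sort keeps
  genome-scale contrasts fast.
- BH caps q at 1 and rejects p outside (0, 1].
- PERMANOVA requires ≥2 levels per factor, ≥2 observations per design
  cell, and rejects confounded factors (empty cells).
- CLR zero-replacement ε is exposed; rows are validated to the simplex at
  1e-6.
- One integer seed per pipeline run derives all stage seeds by fixed
  offsets; reports are bit-identical across reruns of the same config.

## Problem sizes used in validation

The test suite exercises the full default scale (6,272 spots × 5,000
genes) for parameter recovery (5 seeds), depth effects (10 seeds) and DE
null calibration (10 seeds), and smaller grids (typically 14–24 rows) for
structural and pipeline tests; PERMANOVA null calibration uses 200
simulated composition tables of 40 observations at 199 permutations.
These sizes were chosen as the smallest that make the statistical
assertions sharp.

## Known limitations

- Gene identity is by symbol; Ensembl IDs are carried as metadata only.
- No batch integration across slides; slides are normalized jointly.
- The rank-sum normal approximation is anticonservative relative to the
  exact permutation tail for tiny, heavily tied samples; the exact branch
  covers those, but the bulk screening path assumes group sizes in the
  tens or more.
- PERMANOVA permutes raw observations; exchangeability under the full
  model is assumed, as in the reference R implementation's default.
- The composition module accepts any deconvolution output but ships no
  deconvolution of its own.
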