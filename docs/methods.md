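# Methods

## Problem setting

Chromatin accessibility, assayed genome-wide by DNase-seq as DNase I
hypersensitivity (DH), varies across cell types together with the
transcriptome. `birdreg` treats the DH level Y_l of each 200-bp genomic
locus l as a response and the expression profile **X** of the same sample
as the predictor, learning Y_l = f_l(**X**) + ε_l from a compendium of
paired training cell types. The regime is extreme even by high-dimensional
standards: G ≈ 2·10⁴ predictors, C ≈ 40 samples, and ~10⁶ regressions to
fit simultaneously, so every design choice trades statistical efficiency
against computation.

## Signal preprocessing

Raw DNase-seq bin counts n_li (200-bp non-overlapping bins, 0-based
half-open coordinates) are depth-normalized as ñ_li = N·n_li/N_i with
N = min_i N_i, averaged across replicates per cell type on the
normalized-count scale, then log2(x+1) transformed. Expression matrices
are assumed gene-level; they are log2(x+1) transformed, quantile-normalized
across samples (reference = per-rank mean of sorted columns; ties receive
the mean of their tied reference span), and replicate-averaged after
processing. Chromosome Y is dropped by default (absent in many samples).
New samples at prediction time are quantile-mapped onto the stored training
reference; a length mismatch is handled by linear interpolation of the
reference on rank fraction.

Row standardization uses the population (divide-by-n) SD — the convention
cancels in the standardize/unstandardize round trip, and n is chosen for
determinism. Zero-variance rows standardize to 0: a constant gene
contributes nothing, and a constant locus predicts its training mean.

## DHS selection

Candidate bins pass three filters computed on training cell types only, in
order: maximum normalized count strictly > 10 in at least one cell type;
no cell type strictly above 10,000 (abnormal signal); and maximum
log2(SNR) strictly > 2, where the background of a bin is log2(mean+1) of
its 500 nearest same-chromosome bins. The neighborhood excludes the bin
itself, takes 250 bins per side, and slides inward at chromosome ends so
exactly 500 bins are used whenever the chromosome allows; shorter
chromosomes fall back to all other bins with a warning. Whether the
original procedure included the bin itself or how it handled chromosome
ends is not documented anywhere we know of; the convention above is ours
and is exercised against a brute-force nearest-bin oracle in the tests.
The retained index set belongs to the trained model, so test samples are
never consulted.

## The estimator

`BIRD` follows the scikit-learn estimator contract (`fit(X, Y)`,
`predict(X)`, `get_params`, trailing-underscore fitted attributes) with
samples = cell types as rows. Internals:

* **Gene clustering** (K = `n_gene_clusters`, field-scale default 1500):
  k-means with Euclidean distance on standardized expression rows, seeded
  careful initialization, best of `kmeans_restarts` = 3 runs, ≤ 300
  iterations. Empty clusters are dropped and ids re-indexed; cluster means
  are recomputed as exact member means. All k-means seeds derive from
  `random_state` through a `SeedSequence`, making training bit-reproducible.
* **Screening** (N = `n_predictors`, default 7): clusters are ranked by
  |Pearson r| between their mean expression and the locus's standardized
  DH across training cell types; ties break toward the lower cluster id,
  and any correlation involving a zero-variance vector is defined as 0.
  Absolute ranking is a deliberate choice — the magnitude criterion alone
  is ambiguous about sign, and absolute ranking retains informative
  repressive relationships.
* **Per-locus OLS**: minimum-norm least squares (`numpy.linalg.lstsq`),
  which degrades gracefully on rank-deficient designs; an empty predictor
  set degenerates to the intercept (the mean).
* **Pathway layers** (ℋ = `pathway_sizes`, field-scale default
  {1000, 2000, 5000}): standardized DH rows are k-means clustered into H
  pathways; each pathway's mean-activity row is fitted with the same
  screen-then-OLS procedure; the aggregation weight d_l^H is the Pearson
  correlation between locus l's standardized row and its pathway's mean
  row. H = L is special-cased: the layer coincides with the locus-level
  model and d ≡ 1. Entries of ℋ above L are clipped to L with a warning so
  small problems remain usable.
* **Aggregation** happens on the standardized scale; the locus-level layer
  always participates with weight 1, negative d are clamped to 0 by default
  (`clamp_weights`), guaranteeing a denominator ≥ 1 and making the output a
  convex combination of the component predictions. Whether the original
  method clamps is unknown, so the behavior is switchable. The single
  unstandardization s_l·Ỹ + a_l is applied last.

Genes missing from an input sample are imputed at the training mean
(standardized 0) with a warning; below 50% coverage prediction refuses.

Model archives are a directory holding a JSON manifest (parameters, ids,
format version) and one NPZ of float64/int tables; loading reproduces
predictions bit-for-bit on the same platform.

## Evaluation statistics

r_L (per test cell type, across loci), r_C (per locus, across cell types),
and τ = ΣΣ(y−ŷ)²/ΣΣ(y−ȳ)² with ȳ the grand mean of the truth; Spearman
variants rank-transform before correlating. Correlations with a
zero-variance argument are reported NaN, excluded from means and counted —
never coerced to zero in reports (inside the model the 0 convention applies
instead, where a weight or screening score is needed).

The permutation baseline shuffles the cell-type labels of the training DH
matrix, retrains, and evaluates on the untouched test set, 10 replicates by
default. It calibrates how much apparent accuracy comes from locus
propensity alone: r_L stays substantial (each cell type's DH profile is
dominated by the shared propensity landscape) while r_C collapses to ≈ 0.

Differential analysis between two cell types correlates predicted versus
true signed differences δ, over all loci and over "differential" loci
(log2 DH ≥ 2 in at least one of the two cell types, |δ| > 1). Cell-type
pairs are stratified into quartiles of DH-profile similarity (ties to the
lower stratum). Locus stratification labels loci active nowhere as noisy
and median-splits the rest on max−min spread, CV, and cell-type
specificity, operationalized as min(#active, #inactive) — both broadly
shared and broadly absent signals count as unspecific. The active
threshold (log2 DH ≥ 2) reuses the differential-analysis cutoff and is
configurable.

## Binding-site and pseudo-replicate analyses

A motif site's score is the maximum predicted accessibility over
overlapping retained bins (max reflects peak accessibility; sites touching
no retained bin get −∞ and rank last). Curves are computed over distinct
score thresholds with tied blocks processed whole; sensitivity-at-FDR q is
the best sensitivity over thresholds with empirical FDR ≤ q, making the
reported curve a monotone step envelope whose area over [0,1] is the
AUSFC. AUROC uses the standard sweep and equals the pairwise rank
statistic with half credit for ties. Pseudo-replicate integration is the
unweighted elementwise mean of an observed and a predicted log2 track;
with independent comparable noise on both, averaging provably reduces
noise variance, which the simulation test verifies empirically.

## Synthetic-data generator

`simulate` draws: latent module activities A ∈ ℝ^{K_true×C} i.i.d. standard
normal; gene g in module k expresses A_k + N(0, σ_expr); pathway p loads on
`predictors_per_pathway` modules with signed uniform coefficients scaled to
unit ℓ2 norm (unit pathway-activity variance, keeping signal scale
comparable across pathways); locus l in pathway p shows
propensity_l + pathway activity + N(0, σ_DH), with propensity ~
N(0, σ_prop). Loci are laid out as contiguous 200-bp bins on one
chromosome; TSS positions are uniform random, deliberately unlinked to
pathway membership so local (nearest-gene) models carry no advantage. A
Poisson emitter converts log2 signal back to depth-scaled raw counts for
filter tests.

Standard conditions: 40 training / 17 test cell types, 2000 genes in 30
modules, 5000 loci in 50 pathways, σ_expr = 0.5, σ_DH = 0.2, σ_prop = 1.0.
The propensity scale was set so that a propensity-only (label-permuted)
model reaches r_L ≈ 0.6–0.65 — the qualitative signature observed on real
compendia — while cross-cell-type signal has unit variance. The generator
intentionally omits several features of real data: heavy-tailed and
zero-inflated count noise, nonlinear expression–accessibility coupling,
mappability artifacts, and correlated (batch) noise across samples.
Passing recovery tests therefore demonstrates correctness of the
estimator, not the accuracy attainable on real compendia.

## Problem sizes and defaults used in checks

Recovery checks train at K = 100, N = 7, ℋ = {50} on the standard
simulation and across the DH-noise grid {0.2, 0.5, 1.0, 2.0}; the
permutation null uses 1000 loci, 10 test cell types and 10 replicates.
These sizes exercise every code path of the full-scale configuration
(K = 1500, N = 7, ℋ = {1000, 2000, 5000}) while remaining desk-scale.
Under the standard conditions the model reaches mean r_C ≈ 0.85–0.9 and
mean r_L ≈ 0.94 at σ_DH = 0.2, degrading monotonically with noise; the
pathway-activity layer is consistently more predictable than individual
loci, which is what motivates the aggregation.

## Known limitations

* The model predicts only loci retained at training time; it cannot
  discover new DHS locations, and cross-cell-type accuracy at loci with
  little training variation is intrinsically capped.
* Quantile mapping assumes the new sample's expression distribution is
  comparable to the training platform's after rank alignment.
* k-means restarts find local optima; different seeds give slightly
  different (all valid) clusterings, which is why seeds are part of the
  stored configuration.
* The linear model ignores saturating or switch-like expression–
  accessibility relationships. Nonlinear smoothers are substantially more
  expensive at ~10⁶ regressions and have not shown accuracy gains in this
  setting, so they are out of scope here.
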