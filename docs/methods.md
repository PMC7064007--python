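# Methods

This note documents the models, parameter choices and known limitations of
`stemnet`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## Scope and assumptions

The pipeline starts at a gene × sample count matrix: read QC, alignment and
quantification are upstream concerns. GO annotation is treated as flat term
sets per gene — no ontology-graph ancestor propagation and no
graph-decorrelation of enrichment tests. Enrichment is therefore classic
one-sided Fisher/hypergeometric; tools that decorrelate along the GO graph
(e.g. the weight01 algorithm) will return different p-values on the same
input, which is why the package never compares its p-values to numbers
produced by such tools. Water-regime response is deliberately not modeled:
the two regimes serve only to widen the range of biological conditions
behind the correlations.

## Preprocessing

* **Read filter**: keep genes with count > `min_reads` (default 3, read
  strictly: a gene at exactly 3 everywhere is removed) in at least
  `min_samples` (default 20) samples. Filtering operates on raw counts; the
  rule is stated in read units.
* **TMM normalization** (defaults of the published method): reference =
  sample whose upper-quartile count fraction is closest to the mean; for
  each sample, gene-wise log-ratios M against the reference are doubly
  trimmed (30% of M, 5% of the average log-abundance A from each tail) and
  averaged with inverse-asymptotic-variance weights; factors are normalized
  to geometric mean 1. The implementation reproduces reference
  normalization factors from an independent implementation to 1e-9 on a
  frozen fixture (see `tests/test_preprocess.py`). Expression is
  log2(CPM + 1) on effective library sizes; the +1 pseudo-count means CPM
  scaling invariance is exact only for plain CPM and approximate under TMM
  (the precision weights depend on depth).
* **Batch estimation**: gene-wise OLS of expression on sum-to-zero-coded
  nuisance factors (year, block), fitted jointly; the fitted batch terms
  are subtracted and biological factors are left un-modeled. Because of the
  sum-to-zero constraint, the coefficient of a level carrying a planted
  additive offset δ is δ(L−1)/L for L levels; the recovered *effect*
  reported by `BatchEstimate.level_effect` is the contrast
  level-vs-mean-of-others, which equals δ. A factor level that coincides
  exactly with one developmental stage is flagged as confounded (warning)
  but estimation proceeds.

## Network model

* **Correlation**: Pearson, on log-expression; ≥ 3 samples required;
  zero-variance genes dropped with a warning.
* **Adjacency**: default `signed_hybrid`, a = r^β for r > 0 and 0
  otherwise, β = 12. This is the variant consistent with an adjacency
  threshold of 0.1 corresponding to a correlation of 0.82
  (0.82^12 ≈ 0.092 ≈ 0.1 at one decimal; the signed form ((1+r)/2)^12 = 0.1
  would instead imply r ≈ 0.65). `unsigned` and `signed` are implemented
  and selectable.
* **Scale-free fit**: signed R² of log10(frequency) on log10(mean
  connectivity) over 10 equal-width connectivity bins, sign = −sign(slope).
  Equal-width binning is used because with equal-count bins the frequency
  is constant by construction and the regression is degenerate.
* **TOM**: TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij),
  unit diagonal, verified against a brute-force triple loop.
* **Module detection**: average-linkage hierarchical clustering on
  1 − TOM with a *static* cut at height 0.99 (the full dynamic tree-cut
  heuristic is not implemented; the static cut's parameters are exposed and
  planted-recovery tests guard its behavior), minimum module size 30,
  then iterative merging of the closest eigengene pair while its
  correlation exceeds 0.75. Module names come from a fixed color palette
  assigned by descending size (ties by smallest member gene ID) —
  deterministic rather than random color picking, for testability.
* **Eigengenes**: first right singular vector of the gene-standardized
  module expression, unit norm, sign-oriented to correlate positively with
  the module mean profile.
* **Strong-correlation filter**: a gene is retained iff its best
  within-module adjacency reaches the threshold (0.1). The quantifier
  (at least one partner) is a design choice; the threshold alone does not
  determine it. Modules with fewer than `min_retained` = 3 retained genes
  are dropped from the retained map.
* **Connectivity and hubs**: kTotal/kWithin/kOut/kDiff as adjacency row
  sums; hub lists are top-10 and top-⌈10% of module size⌉ by kWithin,
  ties broken by ascending gene ID, computed on all members or on the
  retained subset; the package reports the overlap between the two
  variants.

## Enrichment

Universe = genes entering the network analysis (surviving the read
filter). Per-term upper-tail hypergeometric p-values, exact against
enumeration on small universes; custom-list enrichment is the equivalent
one-sided Fisher test on the 2×2 table. Significance is raw p < 0.05 — no
multiple-testing correction by default, matching the screening character of
the analysis; Benjamini–Hochberg is available as an option. A module is
"CW-related" when it passes both the custom-list test and ≥ 1 cell-wall GO
term — the dual criterion used to select modules for further study.

## Bait subnetworks

Neighbors are ranked by raw signed correlation (for positive r this is the
same order as adjacency under any monotone power); the second layer uses
the same global correlation matrix, not a within-module restriction, since
baits are screened across the whole network. The bait itself is counted in
the union list; this is what makes the theoretical maximum
1 + k + k² = 241 at k = 15. Enrichment categories are read half-open:
none < 3 ≤ light < 6 ≤ medium < 12 ≤ high, with high unbounded above —
the printed category bounds overlap at their endpoints, so a convention had
to be fixed; it is documented here rather than asserted as anyone's intent.

## Biochemistry

hemicellulose = NDF − ADF, cellulose = ADF − ADL, lignin = ADL (%DM); the
three derived fractions telescope back to NDF exactly (to floating-point
rounding). Stage comparison uses pairwise Welch t-tests with Holm
correction — the field data have ~4 replicates per stage and no
homoscedasticity guarantee, so Welch + Holm is a conservative standard
choice — and a compact letter display computed as the maximal
non-significantly-different subsets (maximal cliques; group counts are
small enough for exhaustive enumeration).

## Synthetic data generator

The generator emulates the statistical shape of the field study; its
defaults are the package's study conditions and are not tuned per test.

* **Design**: 191 internode samples in an unbalanced 3-year layout
  (2013: internodes 12/16 × stages D1–D5 × 2 regimes × 4 blocks, without
  the top internode at D1 and with one missing sample; 2014: 12
  internode-stage combinations × 2 regimes × 3 blocks; 2015: 8
  combinations × 2 regimes × 3 blocks). Full-factorial designs are
  available for desk-scale tests.
* **Counts**: each planted module draws a Gaussian-bump latent profile
  over the ordered stage index (width 0.6 stages), standardized; gene
  log2-level = baseline (N(4, 1.5) log2-CPM-scale) + amplitude (2.5) ×
  latent + N(0, σ) noise with σ chosen so the latent share of log-scale
  variance equals the target within-module correlation (default 0.9).
  The first member of each module gets σ scaled by 0.4 — a planted hub
  with the tightest latent coupling, hence the highest intramodular
  connectivity. Levels are renormalized per sample to relative abundances
  and scaled by a log-uniform library size (0.5–2 × 10⁶), then sampled
  negative-binomial with dispersion 0.05. The renormalization gives the
  counts the compositional coupling real RNA-seq has (a surging module
  depresses everyone else's CPM); TMM removes it downstream. Count noise
  erodes the planted correlation slightly, so realized log-CPM correlations
  sit within about ±0.1 of the target at 191 samples.
* **Default gene complement**: 2,000 genes, five modules of 150/100/120/
  60/70 genes peaking at D1/D2/D3/D4/D5, the D3 and D4 modules carrying
  cell-wall annotation rates 0.8 and 0.6 (the SCW analogues), 12 module
  baits + 2 background baits of which one is pinned to ~0.3 expected reads
  per million (exercising the low-expression exclusion path). 2,000 genes
  keeps a full network build in seconds; sizes are configurable upward.
* **Annotation**: a 120-term GO vocabulary of which 17 are cell-wall terms
  grouped under six keywords ("SCW" with 4 member terms, cellulose, xylan,
  lignin, pectin as BP; one CC group), background terms ~Poisson(2) per
  gene.
* **Biochemistry**: logistic accumulation per component with the lignin
  inflection constrained not to precede the polysaccharides'; fractions are
  composed additively (ADL ≤ ADF ≤ NDF holds by construction, noise
  included).

What the generator does *not* emulate: technical lane replicates,
water-deficit differential expression, GC/length biases, ontology
structure among GO terms, and overlapping module membership. Passing tests
therefore demonstrate the correctness and calibration of the machinery on
data satisfying the model's assumptions, not performance on real
transcriptomes.

## Numerical conventions

Ties everywhere break by descending score then ascending gene ID. All
deterministic outputs sort by identifier. Correlation matrices are
symmetrized and clipped to [−1, 1] before use; TOM is clipped to [0, 1].
Percentages round half away from zero. All randomness flows from a single
integer seed per run.

## Problem sizes

The default conditions (2,000 genes × 191 samples) build the full network,
TOM and module set in a few seconds on one core; the acceptance script's
repeated-seed studies (3 seeds for module recovery, 20 for hub recovery,
1,000 resamples for enrichment calibration) complete in well under a
minute. Scaling to ~20,000 genes is a memory/time tradeoff of the dense
TOM (O(n²) memory, O(n³) time) and is feasible but not the default.

## Known limitations

* Static tree cut instead of dynamic hybrid cutting; on weakly separated
  modules the two can differ materially.
* Flat GO annotation overstates term independence; enrichment p-values are
  anti-conservative for nested terms.
* The compact letter display is a presentation convention; with strongly
  unequal variances the Welch/Holm letters need not be transitive-looking.
* The batch estimator is additive-effects-only; it will not remove
  multiplicative or interaction batch structure.
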