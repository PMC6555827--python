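# Methods

This note documents the models and procedures implemented in `nconserve`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Response ratios

An OTU's response at a location is

> log2( (mean normalised count over treatment plots + c) /
>        (mean normalised count over control plots + c) )

with pseudocount c = 0.5 added to the *group means*, not the raw counts.
Normalisation uses median-of-ratios size factors: for each plot, the median
over reference OTUs (those with nonzero counts in every plot) of
count / geometric-mean-across-plots, rescaled to geometric mean 1. This is
the standard library-size estimator for overdispersed count data and an
explicit, hand-checkable approximation to variance-stabilised counts; it
is used here only for normalisation, never for significance testing.
Numerical agreement with any particular differential-abundance package is
not claimed.

Rare OTUs are removed per location before ratios are computed: retention
requires nonzero counts in at least ⌈n_plots/2⌉ plots, i.e. OTUs in
*strictly less than half* of the plots are dropped and an OTU in exactly
half (even n) is kept. Low-occupancy taxa otherwise contribute ratios that
are mostly sampling noise.

Cross-location merging retains OTUs present (post-filter) in at least 5
locations and takes the **unweighted** arithmetic mean of their
per-location ratios, so every location counts equally regardless of
replication or sequencing effort. Ratios of exactly 0 (possible with the
symmetric pseudocount) carry no direction; they are flagged and excluded
from all binary positive/negative analyses.

Design properties guaranteed by construction and enforced by tests:
ratios are invariant to a common scaling of all plots (up to pseudocount
effects), and swapping the treatment/control labels negates every ratio
exactly.

## consenTRAIT

For a binary trait (response direction), the tree is traversed from the
root; a node is a **consensus clade** when the fraction of its descendant
tips bearing the trait is *strictly greater* than the threshold (default
0.9 — a 9-of-10 clade fails, a 10-of-11 clade qualifies) and no ancestor
already qualifies, so reported clades are the deepest (closest to the
root). Trait-bearing tips outside every consensus clade become singleton
clades with depth equal to half the patristic distance to their nearest
tip. τ_D is the unweighted mean of clade depths, **singletons included**
by default (a flag excludes them for sensitivity analysis); clade depth is
the mean node-to-descendant-tip path length. A mean clade depth d implies
roughly 2d expected tip-to-tip dissimilarity within clades (two node-to-tip
paths), which is how a τ_D of 0.018 maps to ~3.6% sequence divergence.

Significance: the trait vector is shuffled across tips (prevalence
preserved) `n_perm` times (default 1000) and P is the plain fraction of
permuted τ_D values ≥ the observed one, so P = 0 is possible; a flag
switches to the (b+1)/(m+1) estimator. No minimum clade size and no
bootstrap-support filter are imposed; support labels are carried through.

The implementation precomputes tree geometry once and evaluates all
permutations as matrix sweeps, which keeps 1000 permutations on a
1000-tip tree well under a second; it is validated against a brute-force
all-node enumeration oracle on hundreds of random trees (exact equality of
clade sets, depths and τ_D).

## Fritz–Purvis D

Nodal values are computed tip-to-root as the mean of the two children's
values (polytomies are first resolved deterministically in child order
with zero-length branches); d_obs is the sum over internal nodes of the
absolute difference between the two children. The scaled statistic is

> D = (d_obs − mean_brownian) / (mean_random − mean_brownian)

where `mean_random` averages d over tip shuffles and `mean_brownian` over
Brownian simulations on the tree (variance = branch length), each
simulated vector binarised at its own empirical quantile so simulated
prevalence equals the observed prevalence exactly — this removes
prevalence as a confounder of the null. P is the fraction of random-null
d values ≤ d_obs (smaller d = more clumped). Calibration simulations
confirm E[D] ≈ 1 for shuffled traits and ≈ 0 for threshold-Brownian
traits within ±0.15 at 128 tips.

## Mantel correlogram

The trait-distance matrix is T(i,j) = |r_i − r_j|. Phylogenetic distances
are partitioned into equal-width classes over [0, max] (Sturges' rule on
the pair count unless overridden); the class-k coefficient is −1 × the
Mantel correlation between T and the class-membership indicator, so a
positive coefficient means pairs in that class respond *more similarly*
than average. Per-class two-sided P values come from `n_perm` (default
999) permutations of the responses; progressive Holm correction (class k
corrected among the first k classes) is applied by default. Empty classes
are dropped with a warning; constant responses are an error. Either
patristic distances or an externally supplied matrix (e.g. alignment
p-distances) may be used; the source is recorded in the result metadata.
Note the two depth scales are not automatically reconciled: patristic
distances on a tree and alignment p-distances agree only approximately.

## Synthetic data

The generator emulates a multi-location field experiment:

* **Trees**: Yule (default) or Kingman coalescent topologies, branch
  lengths rescaled so the mean root-to-tip distance is 0.15
  substitutions/site — the scale of 16S amplicon divergence.
* **Planted clades**: internal nodes with mean depth within ±25% of a
  target are selected greedily and disjointly until ~`prevalence` of tips
  are covered; covered tips respond positively, the rest negatively, and
  each label flips independently with probability `flip_noise`. Effect
  sizes β are lognormal around 2 (log2 units), signed by the final label.
  The default planted depth is **0.05**: at desk-scale tip densities
  (10²–10³ tips) the shuffle null already produces τ_D ≈ 0.02 from random
  cherries and singleton nearest-neighbour distances, so planting at the
  genus-level depth of ~0.018 produces no detectable signal — resolving
  depths that shallow requires the tip density of full amplicon surveys
  (thousands of OTUs). Shallower planting remains available by argument.
* **Counts**: per location, OTUs are present with probability 0.8 (so the
  ≥ 5-location merge filter does real work), baselines are lognormal, the
  treatment expectation is multiplied by 2^β, and counts are
  negative-binomial with dispersion 0.3 (variance λ + 0.3λ², typical 16S
  overdispersion) at 5×10⁴ expected reads/plot, 8+8 plots. At this
  dispersion, pure counting noise leaves a residual mean |log2fc| of ≈ 0.3
  per location even with β = 0; near-Poisson settings (dispersion ≈ 0.02)
  bring it under 0.1.
* **Taxonomy**: ranks are defined by cutting the tree at strictly
  decreasing depths (phylum 0.12 → genus 0.018); nesting is consistent by
  construction.

What passing tests show: the statistics recover planted structure of
matching scale, their nulls are calibrated, and the permutation machinery
is unbiased. What they do not show: robustness to tree-inference error,
compositional artefacts beyond simple depth variation, location-specific
community turnover, or taxonomies that disagree with the tree — all
present in real amplicon data.

## Taxonomic enrichment

Per taxon at each rank, positive vs negative responders are tested against
a fair coin with a two-tailed exact binomial test, defined as twice the
smaller tail capped at 1 (the minimum-likelihood definition is available
behind a flag). Default minimum group size is 5 — below that the test
cannot reach P ≤ 0.05, so smaller groups are untestable. No
multiple-testing correction is applied across taxa by default (results are
reported as raw P with an optional Benjamini–Hochberg flag), matching
common practice of reporting per-taxon exact-test P values directly.

## Pipeline and reproducibility

`run_full_analysis` executes rare-filter → per-location ratios → merge →
consenTRAIT (both directions, per location on each location's pruned tree
and merged on the widespread-OTU tree — one implementation for both
levels) → D-test → correlogram → enrichment, and writes TSV outputs plus
a manifest (parameters, derived per-stage seeds, input digests, row
counts). All stage seeds derive deterministically from one master seed;
re-running an identical config reproduces every output byte-for-byte.
Trees are used as rooted as read — no midpoint re-rooting is performed,
because clade depths depend on root placement and that choice belongs to
the caller.

## Problem sizes

Validation simulations use 256-tip trees for recovery (20 replicates,
1000 permutations), 128-tip trees for D calibration (50 trees, 1000 sims
each), 100-tip trees for correlogram power/size, and 200 runs for null
uniformity — sizes at which the Monte-Carlo error of each check is
comfortably below its acceptance band while the whole suite stays fast.
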