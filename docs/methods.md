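# Methods

This note records the models implemented in `scannotate`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical decisions made where the design was open.

## Co-dependency index (CDI)

For gene *g* and reference feature *k* (a cluster indicator, a grouping
variable, or another gene's binarized expression) over *N* cells:

- "expressed" means **raw count > 0**. Binarization happens on counts, not
  the log layer, because the statistic is deliberately a function of the
  sparsity pattern; mixing datasets of different sequencing depth therefore
  requires depth homogenization first (`downsample_depth`, binomial thinning
  to a common expected total).
- `pi_gk = (n_g / N) * (n_k / N)` is the co-occurrence probability under
  independence with plug-in marginals; the p-value is the **inclusive upper
  binomial tail** `P(X >= I)`, `X ~ Binomial(N, pi_gk)`.
- The tail is evaluated in log space (`binom.logsf`, falling back to a
  log-sum-exp over log-pmf terms when the survival function underflows), so
  perfectly co-dependent markers in large datasets keep finite scores;
  `CDI = -log10 p` is capped at 1e4.
- `nCDI = CDI / CDI_perfect(k)` where the denominator evaluates the tail at
  `I = n_k`, `pi = (n_k/N)^2` — the score of a gene whose expression
  coincides exactly with membership. Values are clamped to [0, 1]. When the
  reference covers all cells the denominator is 0 and `nCDI` is reported
  as 0 (no contrast exists).

**Calibration.** The plug-in binomial null ignores that the margins are
fixed; given the margins, the coincidence count is hypergeometric, whose
variance is smaller by a factor `(1 - n_g/N)(1 - n_k/N)/(1 - pi_gk)`. The
test is therefore slightly conservative for dense features and well
calibrated in the sparse regime it is designed for: with independent binary
vectors at ~10% density the mid-p adjusted p-value is indistinguishable from
uniform (KS, 1,000 replicates), while at ~30–40% density the compression
toward p = 0.5 is detectable. Marker detection (sparse genes, minority
clusters) lives in the calibrated regime.

One-vs-rest marker tables apply Benjamini–Hochberg correction jointly across
all gene × cluster tests (the conservative scope choice). Replicate-aware
markers combine per-group p-values with Fisher's method, χ² = −2·Σ ln p on
2·n_groups df, skipping groups that lack the cluster (df adjusted, warning).

The Wilcoxon/AUROC baseline is a vectorized one-vs-rest rank-sum on the
log-normalized layer with tie-corrected normal approximation and continuity
correction; it matches `scipy.stats.mannwhitneyu(method="asymptotic")` to
machine precision. Genes with non-positive log-fold-change are flagged
`excluded` — the CDI only scores over-representation, so cross-method
comparisons drop them.

**Descriptive metrics.** Sensitivity, specificity, PPV and NPV reduce
algebraically to functions of the within-/outside-cluster expressing
percentages and are descriptive of markers, not of test accuracy. The
cluster-exclusivity ("Gini") index is implemented as
`sum_k(1 - x_gk / max(x_g)) / (n_clusters - 1)` on cluster-mean log
expression — 1 for a gene expressed in a single cluster, 0 for a uniform
gene. An alternative unnormalized variant is retained behind
`printed=True` for auditability; it is not bounded in [0, 1] and is not used
anywhere.

## Two-group simulator and the DE benchmark

`simulate_two_group` draws gene means from Gamma(shape 0.6, rate 0.3),
library sizes from a log-normal rescaled so the empirical mean cell total
equals the target depth, and counts from Poisson. A fraction `de_prob`
(default 0.1) of genes receives a multiplicative Group2 factor with
log-normal magnitude (location = effect size, scale 0.4); **half of the DE
factors are reciprocal** (down-regulation, `de_down_prob = 0.5`), matching
standard gamma-Poisson simulators for this design. Expression proportions
are renormalized per group so library size is not a group confound — the
cost is a small global composition shift in non-DE genes, which a rank-sum
test over thousands of cells can detect; this is a real property of
depth-normalized data, not an artifact to remove. Half of the true DE genes
become **bDEGs** by zeroing their counts in Group1 cells; the rest are
**gDEGs**.

The benchmark grid crosses mean depth {1k, 5k, 20k counts/cell} with DE
factor location {0.3, 0.7, 1.2} at 2,000 genes × 2,000 cells. Down-regulated
gDEGs are the reason a one-sided co-occurrence test scores *below* chance on
graded genes: they are invisible to the Group2 contrast while the rank-sum
ranking (best positive-logFC contrast over both groups) still finds them.

**Known limitation.** At the lowest depth (0.5 UMIs per gene per cell on
average) roughly a tenth of genes carry almost no nonzero counts; bDEGs in
that stratum are unrankable by any method, which caps worst-case binary-DEG
recovery near AUROC 0.93 (CDI) / 0.89 (Wilcoxon) there, while the mid- and
high-depth configurations reach 0.977–0.990 / 0.915–0.970. Conclusions about
the *contrast* between the methods are unaffected.

## Resolution selection

Cells are clustered on a Jaccard-weighted SNN graph (PCA on the top 2,000
most dispersed genes, z-scored; 30 PCs; k = 20 neighbors including self;
KNN ties broken by index) by Leiden optimization of modularity with a
resolution parameter (seed 42, fixed), over a default grid 0.05–3.0. The
Leiden refinement of the Louvain objective is used for its deterministic
seed contract.

Per configuration, the top marker nCDI of each cluster defines the
specificity curve over 101 thresholds; the comparison is inclusive
(`>=`) so the ideal configuration — every cluster holding a perfect marker —
scores exactly S = 1. `S_peak` is the argmax (ties to the smallest
resolution). Elbows are automated: on the post-peak segment, the interior
point of maximal perpendicular distance below the chord (kneedle-style),
called only when the segment drops by ≥ 5% relative; up to two elbows,
found successively. Automation replaces visual inspection for
reproducibility — elbow positions on shallow curves should be treated as
suggestions.

ARI against curated labels uses the standard permutation-model form.

## Miko score

`standardized_module_score` bins genes into 24 equal-count bins by
dataset-average log expression and draws up to 100 control genes per member
from the member's bin (without replacement, member excluded). The per-cell
score is `Z_j = (X_j − Y_j)/sqrt(Var(X_j) + Var(Y_j))` with the variances
taken across member and control feature values within the cell. Two
implementation details matter for calibration:

- **Control aggregation.** `Y_j` averages the per-member control means with
  equal weight per member, mirroring the equal member weights in `X_j`.
  Pooling the concatenated control multiset instead is measurably biased
  (≈ +0.005 on a mean-zero score) when control-list lengths differ across
  bins; the per-member form is exactly unbiased.
- **Null centering.** The within-cell standardization makes `Z_j` a ratio
  whose numerator and denominator correlate, so the null mean of cluster
  scores is slightly positive (up to +0.4 null-SD for 5-gene sets, measured
  on signal-free data). The null model therefore *uses* its fitted mean
  (cubic polynomial in log size) rather than the theoretical zero; the zero
  approximation is available via `NullModel.center = "zero"`.

The null model scores `n_random` (default 30) uniformly drawn gene sets per
size over a 13-point grid spanning 2–100 genes (universe: genes with > 1%
expressing fraction), pools cluster-level means, and fits their per-size
variance with a gamma-family GLM (log link) on a cubic basis in log size — a
curved power-law decay; a linear log-log fit leaves ±20% SD error at the
grid ends. Predictions clip to the fitted size range (nearest-size
extrapolation with a warning outside it).

`M_k = (Z_obs,k − mean_pred(|s|)) / sd_pred(|s|)` is treated as a Z
statistic with two-sided normal p-values; catalog runs apply BH across
cluster × set. On signal-free data, `M_k` for random sets is centered with
unit spread in each size stratum and pooled p-values are uniform — the
size-independence property that makes scores comparable across differently
sized sets. For sets of ≤ 5 genes the normal tail is slightly conservative
(the small-set score distribution is heavy-tailed).

Annotation considers only positive enrichments (`M_k > 0`, FDR < 0.05),
filtered by the **coherent fraction** (fraction of members positively
Pearson-correlated with the per-cell score; default threshold 0.5) and the
**frequent-flier flag** (sets positively enriched in > 75% of clusters;
depletion does not count toward the rate). Clusters with no surviving set
are labeled `unassigned`; word weights are proportional to `M_k` among a
cluster's surviving sets.

## SSN gene-program discovery

Features: genes with expressing fraction > 0.5 in at least one cell cluster
(computed from exact integer counts). Gene-space PCA on the per-gene
z-scored log layer (genes as observations), keeping the smallest number of
components (≤ 50) explaining > 90% of variance; KNN (k = 20, self included)
in that space; Jaccard SNN graph `G`.

Soft power: candidate grid 0.5–5.0 in steps of 0.5 (the wider of the two
ranges stated for this parameter). For each power, connectivity `w_g` (row
sums of `G^power`) is discretized into 20 equal-width bins; empty and
non-positive-center bins are dropped; `log p(W)` is regressed on `log W`
and the smallest power with signed R² < −0.9 wins. If none qualifies the
power with minimal signed R² is used with a warning — desk-scale fixtures
often do not produce hub-dominated (scale-free) connectivity even though the
transform still sharpens their module structure.

Programs: Leiden communities of `G'` over resolutions 0.1–2.0 (step 0.1);
per-gene neighborhood purity is the majority-program share among the gene's
top-20 `G'`-weight neighbors (mode ties resolve toward the gene's own
program — the purity value is unaffected); the chosen resolution is the
**maximal** one whose mean purity meets the 0.8 target (the stated selection
rule; the alternative printed objective is maximized by the worst resolution
and was discarded as inconsistent). Genes with L2-normalized `G'`
connectivity < 0.1 are pruned — note this retains at most
1/0.1² = 100 hub genes by construction, so program *recovery* is evaluated
on the pre-pruning partition and pruning is treated as hub refinement for
annotation.

Annotation uses hypergeometric over-representation with BH correction;
program activity is the standardized module score of each program's genes;
the recovery score against a known catalog is the mean over known sets of
the best Jaccard similarity achieved by any discovered program. The network
layout is a UMAP of `1 − G'` as a precomputed distance (fixed seed), with
the edge list exported above the 0.9 weight quantile.

## Synthetic data: what it does and does not emulate

- `simulate_two_group` reproduces gamma-Poisson count structure, library-size
  variation, graded and binary DE, and the composition shift of normalized
  data. It omits overdispersion beyond the gamma mixture (no per-cell
  biological CV), batch effects, doublets and ambient RNA, so DE power on
  real data will be lower than on these fixtures.
- `simulate_hierarchy` plants exclusive marker blocks per type (zeroed
  outside the type) and graded subtype factors. Construction-time exclusive
  markers are *stronger* than atlas-derived marker sets: annotation
  sensitivity on this fixture stays near 1 even when half of a set is
  corrupted, so passing its robustness checks demonstrates the direction of
  degradation, not the magnitude seen on real atlases.
- `simulate_coexpression` gives each module a graded log-normal per-cell
  activity plus a shared cell-state factor covarying all genes. The shared
  factor plants the weak spurious between-module association structure that
  the scale-free transform exists to suppress; with it, the chosen
  partition's modularity is higher on `G'` than on `G` across fixture seeds.
  The gain is regime-dependent: with hard disjoint module states (no shared
  covariance) there is nothing to prune and the comparison is sign-unstable,
  and with very strong shared covariance (log-SD ≥ 0.8) programs blur
  together. Raw modularity is not comparable between graphs with different
  weight distributions, so the same-partition comparison is the meaningful
  one.

## Problem sizes

Unit and acceptance tests run on 300–400 genes × 400–600 cells fixtures;
the DE benchmark uses the full 2,000 × 2,000 grid with three seeds
(~30 s on one CPU); null-model calibration uses 100 random sets per size for
fitting and 200 scored sets per stratum. Community detection, PCA/KNN and
the UMAP layout are seeded everywhere; re-running any entry point with the
same seed reproduces outputs bit-identically.
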