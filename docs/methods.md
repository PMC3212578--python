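# Methods

## Scores

**AR-score.** Within each sample, genes with a measured value are assigned
mid-ranks 1..n by relative expression level, with rank n for the highest
value; ties receive the average of the ranks they span, which preserves the
total rank sum n(n+1)/2. The AR-score of a set with m measured members is
the mean member rank divided by n. Exact consequences used as test oracles:
the score is confined to [(m+1)/(2n), (2n−m+1)/(2n)]; for any disjoint
partition of all genes, Σ m_s·AS_s = (n+1)/2; averaging over all C(n, m)
subsets gives (n+1)/(2n); and the score is invariant under any strictly
increasing transform of the sample's values. The rank direction (highest
expression → rank n) is the only convention under which a larger score
means higher expression of the set's genes, and is fixed throughout.

Missing entries are excluded per sample: n is the per-sample count of
measured genes and m the count of measured members, so samples with
different missingness remain comparable. A set with no measured member
yields a missing score, never zero.

**Absolute-value variant.** For two-channel log-ratio data, ranking |value|
makes strong down-regulation count toward activity instead of cancelling
strong up-regulation; exposed as score type `ar_abs`.

**ES-score.** The sample's genes are walked from highest to lowest value;
a member gene (hit) raises a running sum, a non-member lowers it by
1/(n−m). The default is the unweighted Kolmogorov–Smirnov form (hit step
1/m); a weighted form (hit step |zᵢ|/Σ_hits|z_j|) is available. The score
is the running-sum value of maximum |deviation|, signed; if the maximal
positive and negative deviations tie in magnitude the one reached earlier
in the walk wins, and ties between equal expression values are broken by
gene order (stable sort). Both choices are arbitrary but deterministic.
m = n leaves the miss step undefined and is rejected.

## Preprocessing

One-channel intensities are gene-wise standardized (subtract the per-gene
mean, divide by the per-gene standard deviation across samples) before
ranking, converting absolute brightness into relative level; without this
step, within-sample ranks order genes by baseline intensity rather than
regulation, and the test suite contains a fixture demonstrating the
difference. The sample standard deviation (ddof = 1) is used — the
conventional choice for z-scoring expression panels; the scores it feeds
are rank-based, so the ddof choice only matters through rank changes, which
it cannot cause (it is a per-gene positive rescaling). Genes with zero
variance or fewer than two measured values are dropped and reported.
Standardization is idempotent to floating-point precision. Two-channel
log-ratios bypass the step (`standardize: off`).

Gene sets are intersected with the matrix's genes before scoring; sets
keeping fewer than `min_genes` (default 5) mapped members are excluded and
listed in a coverage report. Five is a pragmatic floor below which an
average of ranks is dominated by single genes; it is configurable
everywhere it applies. If no set overlaps the matrix at all the run aborts
with a namespace-mismatch diagnosis rather than silently scoring nothing.

## Pathway–pathway correlation and networks

Two overlapping sets correlate spuriously because shared genes enter both
scores. For every unordered pair the intersection is removed, AR-profiles
are recomputed from the two residual sets across all samples, and Spearman
ρ (mid-ranks over samples) of the residual profiles is reported. A residual
set below `min_genes` makes the pair "not evaluable" — recorded with a
reason and excluded listwise from downstream comparisons, never imputed as
0. For disjoint pairs the exclusion is a no-op and the implementation reuses
cached full-set profiles; a brute-force oracle test confirms pair-by-pair
equality. K sets yield K(K−1)/2 evaluated pairs (17,205 at K = 186).

Networks connect pairs with |ρ| strictly above τ (default 0.75); a pair at
exactly τ is not an edge. Isolated nodes are kept, annotated with set
sizes. Edge lists are written with lexicographically ordered endpoints for
deterministic diffs; GraphML export is available for graph tooling.

Global coupling between two datasets is compared by a t-test on the two
vectors of pair coefficients, defaulting to |ρ| (so strong negative
co-regulation counts as coupling) and a paired test (pairs are matched
entities across datasets); signed and two-sample variants are exposed.
Spearman p-values, where shown, use the usual t-approximation with p−2
degrees of freedom.

## Differential testing and FDR

Per pathway, the two groups' scores are compared with a Welch (unequal
variance) two-sided t-test — the safer default when group variances differ,
as they do when a condition attenuates coupling. The Wilcoxon rank-sum test
is provided as the companion for ES-scores, whose bimodal distribution
suits a rank test better than a t-test; at strong planted effects the two
routes call near-identical pathway sets (tested via Jaccard overlap).
"up" means higher scores in the first group of the comparison; swapping
the group order negates every statistic and flips every direction label.

Storey q-values: π0(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05, 0.10, …, 0.95; a
least-squares cubic in λ is evaluated at λ = 0.95 as the smoother
extrapolation toward 1, clipped to (0, 1] (this tracks the classic
smoothing-spline-with-3-df estimator; on a spot check both land within a
few hundredths of each other). Then q_(i) = min_{j≥i} π0·m·p_(j)/j, which
is monotone in p by construction and reduces exactly to Benjamini–Hochberg
when π0 = 1 — an identity the tests verify against an independent BH
implementation. The estimator is deterministic given the p-values; its
sampling noise on uniform p is a few hundredths around 1, occasionally
larger, because the right tail of the p-histogram is thin — a property of
the estimator itself, reproduced by the reference smoother.

Gene-level direction summaries compute one Welch t-test per gene (reused
across pathways) and report, per pathway, the fraction of member genes
with t > 0, overall and restricted to genes with p below a cut (default
0.001); the restricted fraction is missing when no member passes.
Cross-dataset consistency is the Pearson R between two tables' t-scores
over their shared universe.

## Clustering and classification

Hierarchical clustering uses complete linkage on Euclidean distances
between activity profiles (scipy's implementation; deterministic, with
distance ties resolved by cluster index). Classification is a linear-kernel
SVM with C = 1 (no kernel or grid search — the feature space is small and
AR-scores already share a scale) evaluated by leave-one-out
cross-validation. Feature selection by two-group t-test at a p-cut runs
per fold on training samples only by default; the historically common
global pre-selection (select once on all samples, then cross-validate) is
available and labelled, because it leaks label information — the report
always records which mode produced it. A leakage test verifies that
corrupting the held-out sample cannot change its fold's selection.

## Synthetic generator

Pathway k has latent activity a_k ~ N(0, 1) per sample. Pathways are
grouped into consecutive blocks (default size 5) whose latents are
equicorrelated at γ — positive semi-definite for any γ ∈ [0, 1), validated
by Cholesky at construction. A member gene is
√ρ_w·a_k + √(1−ρ_w)·ε with ε ~ N(0, noise_sd²), so at noise_sd = 1 member
genes pairwise correlate at ρ_w and the AR-profile tracks a_k. Background
genes are pure noise. A gene shared by two sets (designated overlap pairs,
default 2 pairs sharing 20% of the smaller set) loads on the average of
the two latents, rescaled to unit variance — this is what gives the
shared-gene-exclusion logic a real test surface. Differential pathways add
δ to each member gene (in gene-sd units) in every condition after the
first; applying the shift at the gene level rather than to the latent
keeps δ's meaning independent of ρ_w (a latent-level shift would scale by
√ρ_w and vanish for uncorrelated pathways). Per-condition ρ_w and γ encode
the normal-vs-tumor contrast: defaults are ρ_w 0.8 → 0.4 and γ 0.8 → 0.3,
the regime where tightly co-expressed, strongly coupled pathways lose both
properties, with δ = 1 on the first 10% of pathways.

The generator is deterministic per seed (single `numpy` Generator, fixed
operation order). What it does *not* emulate: probe-level effects, batch
structure, heavy-tailed or intensity-dependent noise, correlated
backgrounds, or realistic pathway size/overlap distributions. Passing
tests therefore demonstrate correctness of the statistics and recovery of
the planted correlation/shift structure — not performance on any real
platform's artefacts, to which only the rank-invariance properties speak.

Gaussian marginals were chosen deliberately: every downstream statistic is
rank- or t-based, so only the correlation and shift structure matters, and
a factor model makes the implied covariance explicit and checkable.

## Validation problem sizes

The test-suite and acceptance-script runs use: exhaustive AR oracles at
n ≤ 8, m ≤ 4; 186 sets × 20 samples for the pair enumeration; 50 pathways ×
100 samples/condition for decoupling (γ 0.8 vs 0.3); 100 pathways ×
200 samples/condition for co-expression recovery (ρ_w 0.8 vs 0.4, ±0.05
tolerance); 100 pathways, 10 planted at δ = 1, 30 samples/group for differential
recovery (20 replicates in the test suite, 5 in the acceptance script); 30 pathways, 20/group at δ = 3 for
classification. These sizes give each check comfortable statistical margin
while the whole suite runs in well under a minute of compute per module.

## Known limitations

- AR treats all members as activators; pathways regulated by repression or
  post-translationally are mis-scored by design (a variance-of-ranks or
  signed-membership refinement is future work).
- π0 estimation is unstable for small m (< ~100 p-values); for pathway
  panels of a few dozen, forcing π0 = 1 (BH) is the conservative option.
- Network edges are marginal correlations; no claim of direct interaction.
- The GCT reader implements version 1.2 only; probe-to-gene collapsing is
  a fixed highest-mean-row policy, not a platform-aware mapping.
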