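# Methods

This note documents the statistical models, algorithmic choices and
default parameters behind `micronets`, and what the synthetic-data
tests do and do not establish about real sequencing data.

## The data model

A sample k is a vector of non-negative read counts
ω^(k) = (ω₁, …, ω_p) summing to the sequencing depth m^(k).  Depth is
set by the instrument, not the biology, so the counts are
*compositional*: only ratios carry information, and log-ratios
log(x_i/x_j) are invariant to the total.  Every estimator in the
package either works on log-ratio-transformed data (clr), on
log-ratio variances directly (SparCC, proportionality), or is flagged
as compositionally unaware when combined with raw proportions (the
configuration layer emits a warning in that case).

## Preprocessing

**Zero replacement.**  Log-ratios are undefined at zero, so zeros are
imputed first.

- *Multiplicative*: each row is converted to proportions; every zero
  cell receives a small δ and the non-zero cells of a row with Z
  zeros are shrunk by (1 − Zδ).  This preserves the ratios between
  non-zero parts exactly.  Default δ = 0.1 × (smallest observed
  non-zero proportion in the matrix) — small enough to stay below any
  observed signal; user-settable.
- *Bayesian-multiplicative*: counts in a sample are treated as
  multinomial with a Dirichlet(α) prior; zero cells take their
  posterior-mean proportion (c_i + α_i)/(m + Σα) and non-zero cells
  are rescaled to keep the unit sum.  Default α_i = 0.5 (a
  Perks/Jeffreys-style prior), user-settable.  Because sequencing
  zeros are count zeros (they could be non-zero at higher depth),
  this is the recommended method for count data.

**Normalization.**  TSS divides by depth (proportions); CSS divides
by the within-sample cumulative sum of counts up to a quantile
(default 0.5), rescaled by the median of those sums so the output
stays on a count-like scale; COM rescales all samples to the minimum
depth; rarefaction subsamples without replacement (multivariate
hypergeometric) to a common level, seeded; clr maps each row to
log(x/g(x)) with g the geometric mean, so rows sum to zero.

**Filtering** runs samples-first (the depth filter must see original
depths), then taxa.  The sample threshold is inclusive
(depth ≥ minimum).  Ties in top-k-by-frequency are broken by
ascending taxon label so results are deterministic.

## Association estimation

**Correlations.**  Pearson, Spearman (Pearson on average ranks) and
the biweight midcorrelation (Tukey biweights around the column median
with tuning constant 9; columns with zero MAD fall back to Pearson).
Applied to clr-transformed data these are compositionally aware.

**SparCC.**  Log-ratio variances t_ij = var(log(x_i/x_j)) decompose
as t_ij = w_i + w_j − 2ρ_ij√(w_i w_j) in terms of latent basis
variances w.  Assuming taxa are uncorrelated on average, row sums of
t form a linear system in w with matrix (p−2)I + 11ᵀ; solving it and
inverting the decomposition yields correlation estimates.  An inner
loop removes the most strongly correlated pair (|ρ| above the
exclusion threshold, default 0.1) from the system and re-solves, up
to 10 times, to reinforce the sparsity assumption.  Zeros are handled
by Bayesian resampling: each outer repetition (default 20) draws
sample compositions from Dirichlet(counts + 1) and the final estimate
is the element-wise median.  Estimates can fall outside [−1, 1]; the
unclipped matrix is preserved and clipped only for distance
transforms (with a warning).  Components with a negative estimated
basis variance have their correlations set to zero, with a warning.

**Proportionality.**  ρ_ij = 1 − var(g_i − g_j)/(var g_i + var g_j)
on clr columns g; ρ = 1 exactly when two components' logs differ by a
constant.  Note the clr closure induces a small negative bias of
order 1/p between independent components; it vanishes for large
taxon panels.

**Neighborhood selection.**  Each clr column is lasso-regressed on
all others over a 20-point log-spaced penalty grid (λ_max = the
smallest penalty with an empty model, λ_min = 0.01 λ_max).  The
penalty is chosen by StARS: over 20 subsamples of size ⌊0.8n⌋ (for
n ≤ 144, else 10√n), edge-selection frequencies θ give instabilities
2θ(1−θ); their mean over pairs is monotonized from the sparse end and
the densest graph whose monotonized instability stays ≤ 0.05 is
selected.  The two directed coefficient estimates per pair are
combined by an OR rule (default; AND available) and reported as a
signed proxy √(β_ij β_ji) when signs agree (0 on disagreement; the
single available β under OR).  This proxy is *not* a partial
correlation in the exact algebraic sense; it is used because the
model-selection output is an edge set with signed strengths.

## Network construction

Sparsification: hard threshold (strict >, matching "above the
threshold"; an inclusive mode is available), Student t-test
(t = r√((n−2)/(1−r²)), two-sided), or bootstrap (m resamples of the
samples with replacement; exceedances counted under a shifted null
|r_boot − r_obs| ≥ |r_obs|, with a column-permutation null as an
option; p = (b+1)/(m+1) so p-values are never exactly zero).
P-values are adjusted by Bonferroni/Holm/BH/BY or adaptive BH, where
the true-null proportion is Storey's estimate with λ = 0.5.

Distances on selected associations: unsigned d = √(1−r²) (strong
association of either sign → close), signed d = √((1−r)/2) (strong
negative → maximally distant), signedPos (negatives zeroed first).
Similarities s = 1 − d serve as connection-strength weights.  A pair
at s = 0 (e.g. r = −1 under the signed metric) keeps its recorded
distance but is not an edge, since it carries no connection strength.
Unweighted networks use the 0/1 edge indicator as similarity and unit
path lengths; negative-association edges can be excluded.
Soft-thresholding (s = |r|^β or ((1+r)/2)^β, β > 1) yields a fully
connected weighted network; its shortest-path metrics use the
topological-overlap dissimilarity
1 − (Σ_u s_iu s_uj + s_ij)/(min(k_i,k_j) + 1 − s_ij), which is also
available for sparsified networks.

## Network analysis

Shortest paths use dissimilarity weights; degree (weighted = strength),
eigenvector centrality, modularity and the Barrat clustering
coefficient use similarity weights.  Normalizations: deg/(n−1),
2·betw/(n²−3n+2), close/(n−1), eig/max(eig).  The normalized
closeness follows the literal formula; with dissimilarity weights
below 1 it can exceed 1, which is flagged in the output metadata
rather than silently rescaled.  Eigenvector centrality is computed by
power iteration (tolerance 1e-10, ≤ 1000 iterations, sign fixed
positive) on the largest connected component with a diagonal shift so
the iteration also converges on bipartite graphs; other components
get 0.  On disconnected graphs, average path length averages over
connected pairs and closeness sums within-component distances.  Hubs
are nodes above a quantile (default: empirical 95%) of a centrality
distribution (default: eigenvector); the log-normal option fits by
maximum likelihood to the positive values.  Clustering: greedy
modularity (similarity-weighted), hierarchical on the dissimilarity
matrix (non-edges at distance 1; single/complete/average/ward
linkage, cut by k or height), and Girvan-Newman edge-betweenness
removal stopping at the maximum-modularity partition.  Isolated
nodes are labeled 0 and enter modularity as singletons.

## Comparison machinery

Group comparisons re-run the *entire* construction + analysis
pipeline per label permutation — the null hypothesis concerns the
full estimation procedure, not just the final metric.  Two-sided
p-values use the pseudo-count convention (b+1)/(m+1).  Taxa filtering
happens once on the joint matrix so both group networks share a node
set.  Node-wise centrality p-values are adjusted (default adaptive
BH).  Jaccard similarity of most-central sets (default: above the
empirical 75% quantile) is referred to a hypergeometric null with
fixed set sizes; the universe defaults to the nodes connected in
either network (overridable) because the notion of "present taxa" is
otherwise ambiguous.  The adjusted Rand index uses the standard
pair-counting form with a uniform label-permutation null, two-sided
via |ARI|.  Both tests measure departure from *random* agreement;
they cannot certify that two sets or clusterings are different.

Differential associations: Fisher's z-test
((atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), normal reference) for
correlation-type measures only; a label-permutation test for any
measure (used by default for proportionality and partial
correlations).  Plain label permutation is used — the cited
resampling procedure's recentering details are not specified, and
label permutation is the exact null for exchangeable samples.  The
differential network connects pairs with adjusted p ≤ α, weighted by
|r₁ − r₂| (the weight is this package's choice; only connectivity is
prescribed).

## Sample dissimilarity networks

Between-sample distances: Euclidean, Bray-Curtis, Kullback-Leibler
symmetrized as Jeffrey's divergence (the asymmetric KLD is not
exposed because downstream machinery requires symmetry),
Jensen-Shannon (mixture form), Aitchison (Euclidean on clr rows), and
a compositional KLD implemented as the scale-invariant symmetric
divergence (p/2)·log(mean(x/y)·mean(y/x)) — zero iff the two
compositions are proportional; this specific form is this package's
interpretation, chosen for symmetry and compositional invariance.
Only Aitchison and the compositional KLD are compositionally aware;
the others warn on raw compositions.  The matrix is scaled by its
maximum off-diagonal entry to [0, 1], so s = 1 − d is well defined,
and sparsified by k-nearest neighbors with a union rule (an edge
survives if either endpoint lists the other among its k nearest;
ties at the k-th neighbor are all included), so no node drops below
degree k.  Default k = 3; default clustering for sample networks is
hierarchical with average linkage.

## Synthetic data

The generator draws a sparse precision matrix Ω on a chain, block
("cluster") or Erdős–Rényi support with entries ±0.3 (user-settable),
makes it positive definite by a diagonal shift, inverts and rescales
to a unit-diagonal latent correlation R (condition number capped at
100 by convex shrinkage toward the identity when needed).  Latent
log-abundances are N(μ, R) with taxon means μ ~ N(0, 3.5²) — the
spread that produces realistic zero fractions (roughly 30–70% at
p = 50 with depths 1000–50000); compositions arise by softmax and
counts by multinomial sampling at depths uniform on (1000, 50000).
Ground truth (R, Ω and its support) refers to *latent-scale*
associations.  Two-group scenarios either redraw from the identical
model (the null), rewire exactly `magnitude` support pairs
(alternating edge deletions and insertions so the changed-pair list
has length `magnitude`), or scale all edge strengths.

What the synthetic model does *not* emulate: taxonomic correlation of
abundances, overdispersion beyond the logistic-normal level,
batch/covariate structure, and structural (biological) zeros.
Passing tests therefore demonstrate correctness of the estimators
under the logistic-normal-multinomial regime, not performance
guarantees on arbitrary real surveys.  Notably, taxa whose expected
counts are far below one read are informationally erased by the
measurement layer; structure-recovery checks therefore feed the
estimator clr-scale data directly from the latent graphical model,
which is the estimator's own operating scale.

## Verification problem sizes

The statistical calibration layer uses 200 null simulations (p = 15,
two groups of 60, 100 permutations) for the network-comparison
type-I error, 2000 replicates for Fisher-z null uniformity, and 100
simulations (p = 10, 100 permutations) for the differential
permutation test; structure recovery uses a 15-node chain at n = 500
and a 20-taxon independent panel at n = 2000.  Oracle equivalence
covers all non-isomorphic graphs on up to 6 nodes plus 20 random
weighted graphs on up to 8 nodes, against enumeration-based
reference implementations.

## Known limitations

- SparCC's correlation matrix is not guaranteed positive definite.
- The neighborhood-selection edge values are proxies, not calibrated
  partial correlations.
- Permutation comparisons re-estimate networks per shuffle and are
  therefore computationally heavy for expensive measures (SparCC,
  neighborhood selection); permutation counts are configurable.
- The t-test sparsifier assumes approximately normal scores for the
  correlation; for SparCC-type estimates the bootstrap is preferable.
- `fdrtool`-style local FDR and variance-stabilizing transformations
  are not implemented.
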