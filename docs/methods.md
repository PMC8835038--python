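# Methods

## Model and procedure

**Invariant measure of expression on the interaction network.** Expression
values ge_i ≥ 0 (linear scale; log-scale inputs with negatives are rejected,
not shifted) on a fixed, connected interaction network define a Markov chain
whose transition probability from gene i to neighbor j is
p_ij = ge_j / Σ_{k∈N_i} ge_k. Its stationary distribution is available in
closed form, π_i ∝ ge_i · Σ_{j∈N_i} ge_j, normalized by Z to a probability
vector, and the implementation verifies πp = π to 1e-10 in tests. π is
invariant to a global rescaling of a sample's expression (Z absorbs the
square of the factor), so array-level scale differences between samples do
not affect distances. A neighborhood with zero total expression makes the
chain ill-defined; this is an error by default, with optional ε-smoothing
(add ε × mean positive expression to all genes) for data containing exact
zeros.

**Exact W1 on the network.** The ground metric is the unweighted
shortest-path hop distance; it makes W1 a true metric on node distributions
and is exposed as a pluggable matrix so edge-weighted costs can be swapped
in. W1 is computed exactly, not by entropic approximation, because the
distances feed hierarchical clustering where small perturbations can flip
merge order. For the hop metric the solver uses the Beckmann min-cost-flow
formulation (one signed flow variable per network edge, HiGHS LP), which is
equivalent to the full coupling problem but has 2|E| rather than n²
variables; for a generic metric matrix the dense coupling LP is solved
instead. Pairwise distance matrices batch many decoupled flow LPs into one
block-diagonal LP (batch 64) purely for speed — the blocks are independent,
so every pair still attains its own optimum, and tests assert the batched
and single-pair routes agree to 1e-10. When the network is a tree the flow
is unique (the flow on each edge equals the net mass imbalance of the
subtree below it), so W1 is evaluated in closed form as the sum of absolute
subtree imbalances; tests check this path against the coupling LP on random
trees. Solutions are clipped at zero to absorb solver round-off on
identical inputs.

**Clustering and model selection.** Agglomerative clustering (average
linkage by default — the standard choice for precomputed non-Euclidean
distances; single and complete are available) is cut by applying the first
n−k merges of the tree, which always yields exactly k clusters even when
merge heights tie (threshold-based cutting does not). The number of clusters
maximizes the mean silhouette s_i = (b_i − a_i)/max(a_i, b_i) over k in
[2, 15] (the range brackets typical panel structure); items in singleton
clusters get s_i = 0, the common convention where the formula is undefined;
exact ties in mean silhouette go to the smaller k.

**Drug feature network.** Descriptors with any missing value are dropped, as
are near-constant descriptors (most frequent value in ≥ 95% of drugs — a
conventional near-zero-variance cut, overridable). Redundancy reduction
clusters descriptors on 1 − |Spearman ρ| (average linkage, tree cut at
exactly the target count) and keeps, per cluster, the member with the
highest average absolute correlation to the rest (ties → lowest column
index). The feature network is the support of the graphical-LASSO precision
estimate on standardized descriptors (edge iff |Θ_ij| > 1e-8); the penalty λ
is either set directly or chosen as the smallest grid value whose largest
connected component holds at most a third of the features, mirroring the
reduction of a full descriptor set to a smaller connected core. Because
descriptors can be negative, each is min–max scaled to [0, 1] across drugs
before a drug's values on the LCC are normalized to sum 1. No invariant
measure is applied on the drug side: the feature network encodes
statistical conditional dependence, not mass-action interaction, so the raw
normalized feature mass is the distribution transported.

**Prediction.** Each (cell cluster, drug cluster) pair contributes a design
with one row per observed (cell, drug) response and features = the cell's
gene vector ∥ the drug's scaled descriptor vector. Random forests use 100
trees, min leaf 5, mtry = ⌊p/3⌋ (floor, minimum 1) — regression-forest
conventions. Cross-validation is 3-fold at the pair level (matching the
pair-count framing of panel studies; a cell-line-blocked mode would measure
a different, stricter generalization and is out of scope). Folds come from a
seeded permutation; every row gets exactly one out-of-fold prediction, and
predictions are deterministic given (design, seed). R is the Pearson
correlation of predictions and observations (undefined/NA when predictions
are constant) and R² = 1 − SS_res/SS_tot; per-cluster predictions are
concatenated before the overall R/R² so that between-cluster level
differences count toward explained variance.

**CDCN baseline.** The dual-layer closed form predicts a pair from all other
observed entries of its row and column within the paired cluster:
ŷ(c,d) = [Σ_{c'≠c} w_cc' y(c',d) + Σ_{d'≠d} v_dd' y(c,d')] /
[Σ w_cc' + Σ v_dd'], a single observed-entry-weighted average with no extra
mixing parameter (the simplest reading of the dual-layer literature; a
per-layer α-mix is a possible variant but is not implemented to keep one
canonical form). Wasserstein distances become similarities through a
Gaussian kernel with the median off-diagonal distance as bandwidth (the
median heuristic — scale-free and parameter-free); the Pearson variant uses
nonnegative-clipped correlations of the raw feature vectors. Diagonals are
zeroed so a pair never predicts itself; predictions are invariant to a
common positive rescaling of all weights.

**Post-analysis.** Gene importance is out-of-bag permutation importance
(mean increase in OOB squared error when the feature is permuted, averaged
over trees — the accuracy-based notion; impurity importance is biased toward
high-cardinality features). Descriptor features participate in the fit but
are excluded from the gene ranking. The top-n (default 200) genes get a
Welch two-sided t-test between sensitive and resistant cell lines — defined
by splitting the cluster's cell lines at the median of their mean observed
log(IC50) over the cluster's drugs, since differential expression only makes
sense against a response contrast — with Bonferroni correction over exactly
the n tests. Enrichment is the exact hypergeometric upper tail
P[X ≥ overlap] per gene set (sets intersected with the universe first) with
Benjamini–Hochberg FDR across sets.

## Synthetic study conditions

The generator emulates the *shapes* of a pharmacogenomic panel, not its
biology. Defaults: 120 cell lines × 40 drugs in 4 × 3 planted clusters on a
60-gene preferential-attachment network (attachment 2) and 60 descriptors;
10% of responses missing completely at random.

* Expression: LogNormal(0, 0.25) baseline; cells of cluster g get an e^δ
  multiplicative shift (δ = 1.0) on a cluster-specific contiguous gene
  module. δ = 1 is roughly a 2.7-fold module up-regulation — a strong but
  realistic group effect on a microarray intensity scale.
* Descriptors: a chain Gaussian graphical model (partial correlation 0.45,
  known precision used as ground truth in support-recovery tests) with a
  +2 sd mean offset on the drug cluster's descriptor block; constant,
  near-constant and missing-value junk columns are injected to exercise
  cleaning. 60 descriptors (20 per cluster block, mirroring the 20-gene
  modules on the cell side) keep the per-block mass signal well above the
  per-descriptor noise after min–max scaling; with fewer descriptors per
  block, average-linkage clustering occasionally misplaces borderline drugs
  even when the W1 distances separate every drug correctly.
* Responses: y(c,d) = B[g(c), h(d)] + Σ β·z(feature) + N(0, σ²) with
  B ~ N(0, 2²) per paired cluster, σ = 0.5, and — crucially — the identity
  of the informative genes/descriptors drawn separately for every paired
  cluster. This cluster-specific-effects construction is what makes
  per-cluster models genuinely better than a pooled model: no single
  feature→response mapping is shared across clusters.
* All randomness flows from one scenario seed through per-stage spawned
  generator streams; every output is a pure function of (scenario, seed).

What passing on these data does *not* show: robustness to batch effects,
to non-random missingness, to measurement noise that correlates with
expression level, or to real descriptor distributions (heavy-tailed, mixed
discrete/continuous). The synthetic clusters are also cleaner than real
panel structure, so recovered-vs-planted agreement here is an upper bound on
real-data behavior.

For the synthetic chain-GGM descriptors the feature-network penalty used by
the test suite and the reproduction script is λ = 0.2, at which the
estimated network spans all descriptor blocks (the grid-based LCC rule,
designed for the 500→165-style reduction of real descriptor sets, prunes
the small synthetic network too aggressively); λ remains a flag everywhere.

## Problem sizes and numerical choices

Tests and the reproduction script run at desk scale: recovery trials use 30
cell lines / 40 drugs / 60 genes, the prediction comparison uses the default
120 × 40 scenario, and oracle cross-checks use ≤ 12-node graphs where the
brute-force coupling LP is cheap. Key tolerances: stationarity 1e-10 (∞
norm), W1 vs LP oracle 1e-8, silhouette vs brute force 1e-12, graphical
LASSO convergence 1e-6 with a 200-iteration coordinate-descent cap (when
the duality gap has not closed at the cap — common for weak penalties with
fewer samples than features — the residual gap is orders of magnitude below
the edge threshold and the estimated support is unchanged by further
iterations, so the non-fatal warning is tolerated), precision-edge
threshold 1e-8.
Degenerate inputs: constant observed responses make R/R² undefined (error);
constant predictions give R = NA with R² still reported; an all-equal
distance matrix yields silhouette 0 for every k and the selection rule
returns k_min.

## Known limitations

* The W1 solver targets desk-scale problems (≲1,000 items on ≲1,000-node
  networks); pairwise matrices scale quadratically in items.
* Pair-level CV shares cell lines and drugs across folds; reported R²
  measures interpolation within a panel, not transfer to unseen cell lines.
* The CDCN similarity kernel bandwidth uses the median heuristic; no
  bandwidth tuning is performed.
* Enrichment is a generic GMT-based hypergeometric test; ontology-specific
  resources and their curated statistics are out of scope.
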