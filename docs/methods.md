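# Methods

## The model

`k2tax` estimates a binary, taxonomy-like hierarchy over *items* — either
individual observations (samples, cells) or pre-labeled groups of
observations (e.g. single-cell clusters) — from a features × observations
expression matrix. Unlike bottom-up agglomeration, which commits to a
single global feature set, each partition of the recursion is estimated
from features selected *within* the item subset being split, so nested
structure driven by locally discriminatory transcriptional programs
remains visible at every level.

At a node with N items, one partition is estimated as follows, repeated
for p perturbations (default p = 100):

1. **Feature bootstrap** — resample the F features with replacement
   (consensus-clustering style bagging).
2. **Feature selection** — keep the top `round(sqrt(F))` features of the
   bootstrapped matrix by a variability statistic computed over the node's
   observations only. The square-root rule is the random-forest heuristic:
   1,000 features → 32 kept (3.2%), 10,000 → 100 (1.0%).
3. **K = 2 clustering** — observation mode: Ward (configurable linkage)
   agglomeration of Euclidean distances, cut at K = 2; group mode:
   constrained K-means with all observations of a group must-linked.

The p dichotomous ±1 assignments form an N × p matrix. Pairwise
similarity of two items' assignment vectors X_i, X_j is their cosine

    CS(X_i, X_j) = (X_i · X_j) / p = 1 − 2Z/p,

with Z the number of mismatched positions — the Hamann similarity, equal
to the Pearson correlation of the standardized vectors (r = 1 − d²/2p).
The aggregate partition is the K = 2 cut of hierarchical clustering of
the distance matrix D = 1 − Q, by default with *average* linkage — the
consensus-matrix convention. Average linkage follows mean ensemble
similarity, so when the perturbations split between two candidate
bipartitions the majority wins; Ward's variance-based Lance–Williams
update inflates singleton-to-cluster distances and can cut along a
minority bipartition (we observed exactly this on a 4-item node whose
modal 49/100 assignment was discarded in favor of a 46/100 one). The
perturbation-level clustering itself defaults to Ward; both linkages are
user-selectable.

**Partition stability.** With Λ = (λ₁ ≥ … ≥ λ_N) the eigenvalues of Q and
v_k = Σ_{l≤k} λ_l / N the cumulative variance explained,

    PS = max_k (v_k − k/N).

PS = 0 when assignments are mutually random (Q ≈ I) and PS = 1 − 1/N when
every perturbation induces the same bipartition (λ₁ = N); at N = 2 the
maximum is 0.5. PS can serve as a stopping rule (`stability_min`).

**Branch heights.** For a node reached through m partitions with
stabilities PS₁…PS_m (including its own),

    h_m = log(N_m) + Σ_{l=1..m} log(PS_l) + c   (natural log),

where the single per-tree constant c places the minimum *internal* node
height at exactly 1. Heights strictly decrease from root to leaf because
N shrinks and log(PS) ≤ 0. Terminal leaves are not partition nodes and
have no height of their own under this formula; for Newick export they
hang at half their parent's height, giving strictly positive branch
lengths. The per-node partition count includes the node's own partition;
counting ancestors only would shift every height by one log(PS) term and
leave the ordering, and hence every tree cut, unchanged.

**Stopping rules.** A node becomes a leaf when it has fewer than
`min_items` items (default 3 in observation mode, 2 in group mode), when
PS < `stability_min` (default 0, i.e. disabled), when more than half of
its perturbations are unsplittable ("degenerate", e.g. all selected
features constant after 10 resampling attempts), or in the measure-zero
event PS ≤ 0 exactly (which the height formula cannot absorb).

## Constrained K-means as weighted centroid K-means

Group mode must-links every observation of a group. For *complete*
must-link blocks the constrained problem reduces exactly to K-means over
group centroids weighted by group size: a block's cost of assignment to
centroid c decomposes as size × ‖centroid_block − c‖² + a constant
independent of the assignment. We therefore run seeded k-means++
(10 restarts, tol 1e−6, ≤ 300 iterations) on the G × k centroid matrix
with `sample_weight` = group sizes; the equivalence is verified against a
brute-force weighted bipartition oracle in the test suite. Two groups are
split directly (the K = 2 solution is forced).

## Feature-selection statistics

* `sd` (default): sample standard deviation, the statistically efficient
  choice under near-Gaussian noise.
* `mad`: median absolute deviation, robust to outliers. Note its 25%
  breakdown point: a bimodal feature whose minority mode holds fewer than
  a quarter of the observations has a MAD at the noise floor, so features
  tracking very unbalanced splits are invisible to MAD ranking. This is
  why `sd` is the default.
* `f`: one-way between/within variance ratio across the groups at the
  node (ordinary F, unmoderated), available in group mode and used by the
  bundled benchmark, where group labels are known by construction.

Ties are broken by feature order; ranking happens on the bootstrapped
matrix, so duplicated rows legitimately compete as separate features.

## Randomness discipline

One master seed determines everything. Child seeds derive from
`SeedSequence(master, spawn_key=(node_key, perturbation, attempt))`, with
`node_key` a CRC of the node's sorted member ids, so a node's ensemble is
invariant to traversal order and to how many perturbations other nodes
consumed. Two runs with the same configuration produce byte-identical
`taxonomy.json`.

## Subgroup annotation

Each internal node defines a two-subgroup comparison (side A = first
child).

* **Differential expression**: per-feature two-group linear model with
  empirical-Bayes variance moderation. Residual variances s²_g (df d) are
  shrunk toward a scaled inverse-chi-square prior whose parameters
  (d₀, s₀²) are fitted by moments on log s²_g (digamma/trigamma
  identities, Newton inversion of the trigamma); the moderated
  t = effect / √(s̃² (1/n_a + 1/n_b)) has d + d₀ degrees of freedom.
  Underdispersed log-variances yield d₀ = ∞ and the common variance
  mean(s²). The implementation is checked against an independently coded
  oracle and against the Bioconductor reference implementation to 1e−8.
  Sides with fewer than two observations fall back to the ordinary
  pooled t with a logged warning.
* **Signatures**: up-regulated features with q < 1e−10, own-side mean
  above 0.5 (log₂ scale) and positive effect, ranked by q then |t|,
  capped at 50 genes. The expression floor is evaluated on the
  signature's own subgroup.
* **Over-representation**: one-sided upper-tail hypergeometric test of
  signature/gene-set overlap within the matrix's feature universe; sets
  with no overlap with the universe are skipped with a warning.
* **Projection scores**: per observation, features are ranked (average
  ranks on ties) and a set's score is
  (mean in-set rank − mean out-of-set rank) / (F/2) ∈ [−1, 1] — a
  deliberately simple, rank-based single-sample statistic, invariant to
  any monotone transform of the observation's profile, in place of
  kernel-ECDF projection methods. Sets with fewer than two present
  features score NaN. Partition-level differential analysis of the score
  matrix reuses the moderated t machinery.
* **Phenotype tests**: Student's t or exact Wilcoxon rank-sum (exact for
  total n ≤ 40) for continuous variables; Fisher's exact test for 2-level
  categorical variables and a seeded Monte-Carlo permutation p (10⁵
  draws, observed table included in the numerator and denominator) for
  more levels. Constant variables report p = 1 with a flag.
* **FDR**: Benjamini–Hochberg within each analysis; NaN p-values are
  dropped and reported.

## The synthetic-data generator

`simulate_hierarchy` draws a random full binary tree over
`n_terminal_clusters` leaves, splitting each internal node binomially
with the minority side constrained to at least a quarter of the leaves.
`round(signal_fraction × n_features)` signal features are divided among
the internal branches proportionally to each branch's leaf count (≥ 1
per branch); each branch feature receives an antisymmetric mean shift:
+effect_size on one descendant side and −effect_size on the other, the
sign per feature random. Observations are allocated near-evenly to
terminal clusters (remainder round-robin) and iid Gaussian noise with
`noise_sd` is added to every entry. Defaults: effect_size 1.0 (log-scale
units), noise grid 0.5–3.0.

Three generator choices warrant explanation, all consequences of a
single requirement — that the induced hierarchy be *identifiable* by a
top-down K = 2 procedure, so that recovery measures method performance
rather than generator ambiguity:

* *Near-balanced splits.* With one cluster hanging off the root of a
  structured majority, the globally optimal K = 2 split of the noiseless
  data (brute-force weighted within-cluster sum of squares) is provably
  not the generating split: the lone cluster gets absorbed into the
  nearer half of the majority. No clustering method can recover such a
  tree from the data, so the generator avoids producing it.
* *Leaf-proportional feature allocation.* Equal features per branch make
  a deep pair of siblings exactly as close as a cross-root pair,
  producing ties at the root split; weighting by leaf count restores a
  strict margin.
* *Antisymmetric shifts.* Shifting only one side makes a branch's
  features bimodal over a fraction of the observations that depends on
  which side was drawn, decoupling a feature's variance from its
  branch's level in the tree; the ± form keeps branch-level variance
  ordered by tree level, which is the premise of variability-based
  selection.

What the generator does *not* emulate: count overdispersion, dropout,
library-size or batch variation, correlated noise, or unbalanced group
sizes. Passing recovery tests therefore demonstrates correctness of the
partitioning machinery under block-signal Gaussian conditions, not
performance on raw single-cell counts, which are expected to be
normalized, log-transformed and clustered upstream.

## Evaluation metrics

* **Baker's gamma**: for each leaf pair, the number of partitions from
  the root down to (and including) the pair's lowest common ancestor;
  the statistic is the Spearman correlation of the two trees' pairwise
  depth vectors (1 = identical structure). Pairs inside a multi-item
  leaf take the leaf's depth. If either depth vector is constant (e.g.
  two leaves), the value is 1 when the vectors coincide and 0 otherwise.
* **Conditional entropy**: Σ_c (n_c/N) Σ_l −p_{l|c} log₂ p_{l|c} over a
  tree cut's clusters; 0 iff clusters are label-pure, non-increasing
  under refinement.
* **Tree cuts**: K clusters by repeatedly opening the highest remaining
  internal node (ties by node id).

## Benchmark

`benchmark()` crosses noise sd × cluster count, simulates `replicates`
data sets per cell, and compares group-mode ensemble partitioning
(F-statistic selection) against Ward agglomeration of per-group mean
profiles over all features. Cells are scored by mean Baker's gamma
against the generating tree and tested with the paired Wilcoxon
signed-rank (p = 1 by convention when all differences are zero),
BH-corrected across cells. The bundled acceptance configuration runs a
desk-scale grid — noise {0.5, 1.0, 2.0} × {4, 8} clusters, 200
observations, 2,000 features, 5 replicates — sized to finish in minutes
on one core while preserving the qualitative contrast of interest.

## Numerical notes and limitations

* Eigenvalues of Q come from the symmetric solver; magnitudes below
  1e−10 are clipped to zero before cumulative sums; asymmetry beyond
  1e−8 is an error.
* Aggregate clustering of D = 1 − Q clips tiny negative distances to 0;
  an all-tie distance matrix falls back to splitting off the first item.
* K-means nonconvergence returns the best-so-far solution (warning
  suppressed into the ensemble's bookkeeping); a perturbation whose
  selected features cannot separate the items is resampled up to 10
  times, then dropped.
* The recursion is exact, not heuristic, in its bookkeeping — but the
  underlying split estimates remain local optima of their clustering
  objectives; there is no global guarantee for N > 2.
* Group mode treats the supplied labels as fixed truth; label noise
  propagates into the taxonomy.
* Runtime scales roughly as p × (number of internal nodes) × cost of one
  selection + clustering pass; observation mode over thousands of cells
  is substantially slower than group mode over tens of clusters.
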