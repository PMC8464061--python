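# k2tax

Ensemble recursive K=2 partitioning for taxonomy discovery in bulk and
single-cell transcriptomics (and other omics) data.

## The problem

Most clustering pipelines deliver a *flat* set of subtypes. But samples —
and especially cell populations — are often related at several resolutions
at once: lineages contain sublineages, subtypes share programs with distant
subtypes, and the genes that separate two branches near the root are not
the genes that separate siblings near the leaves. A single global feature
set (the premise of ordinary hierarchical clustering and of trajectory
methods) cannot expose that nested structure.

`k2tax` builds a binary, taxonomy-like hierarchy top-down. At every node it

1. bootstraps the features and keeps the `round(sqrt(F))` most variable
   ones *within the current item subset*,
2. runs a K=2 clustering (Ward on Euclidean distances for samples;
   constrained, must-linked K-means for pre-labeled groups such as
   single-cell clusters),
3. repeats this p times and aggregates the p dichotomous ±1 assignments
   into a cosine (Hamann) similarity matrix
   `Q_ij = (X_i · X_j)/p = 1 − 2Z/p`, whose K=2 tree cut is the partition,
4. scores the partition's robustness with the closed-form stability

       PS = max_k ( v_k − k/N ),    v_k = Σ_{l≤k} λ_l / N,

   where λ are the descending eigenvalues of Q. PS is 0 for random
   assignments and 1 − 1/N when every perturbation agrees (0.5 at N = 2).

Branch heights follow `h_m = log N_m + Σ_{l≤m} log PS_l + c`, with c
chosen so the minimum node height is exactly 1. A full annotation suite
(moderated-t differential expression, signature derivation, hypergeometric
gene-set enrichment, rank-based single-sample projection scores, phenotype
tests, BH FDR) characterizes every subgroup, and a simulation/benchmark
harness with Baker's gamma and conditional-entropy metrics evaluates
recovery. See `docs/methods.md` for the full model description.

## Worked example

Simulate a 6-cluster hierarchy (120 observations, 1,000 features, unit
effect size, noise sd 1.0) and rebuild it in group-level mode:

```python
import numpy as np
from k2tax import K2Taxonomer, SimulationSpec, simulate_hierarchy, bakers_gamma

spec = SimulationSpec(n_observations=120, n_features=1000,
                      n_terminal_clusters=6, signal_fraction=0.2,
                      noise_sd=1.0, seed=0)
matrix, truth, labels = simulate_hierarchy(spec)

est = K2Taxonomer(n_perturbations=50, random_state=0)
est.fit(matrix.values.T, groups=labels)      # samples x features

print(f"root partition stability: {est.stability_:.3f}")
for node in est.taxonomy_.internal_nodes():
    left, right = node.children
    print(f"  {node.node_id}: N={node.N_m}  PS={node.PS:.3f}  "
          f"h={node.height:.2f}  split {len(left.member_items)}|{len(right.member_items)}")
print(f"Baker's gamma vs generating tree: {bakers_gamma(est.taxonomy_, truth):.3f}")
```

which prints:

```
root partition stability: 0.833
  n0: N=6  PS=0.833  h=3.55  split 2|4
  n1: N=2  PS=0.500  h=1.76  split 1|1
  n4: N=4  PS=0.720  h=2.82  split 3|1
  n5: N=3  PS=0.649  h=2.10  split 2|1
  n6: N=2  PS=0.500  h=1.00  split 1|1
Baker's gamma vs generating tree: 1.000
```

Reading the output: the root split of the 6 groups is highly consistent
across perturbations (PS = 0.833, close to its ceiling 1 − 1/6); forced
two-group splits sit at the N = 2 ceiling of 0.5; the lowest internal node
has height exactly 1 by construction; and the recovered topology matches
the generating tree exactly (Baker's gamma 1.0).

`K2Taxonomer` follows scikit-learn conventions (`fit`, `labels_`,
`get_params`/`set_params`, works with `clone`); `est.cut(K)` returns the
K-way tree cut, and `est.taxonomy_` exposes the full tree. The same
machinery is available functionally (`run_taxonomy`, `RunConfig`) and from
the shell:

```sh
k2tax simulate --spec spec.yaml --out sim/
k2tax run --matrix sim/matrix.tsv --mode group --groups sim/labels.tsv \
          --out out/ --perturbations 100 --seed 42
k2tax annotate --taxonomy out/taxonomy.json --matrix sim/matrix.tsv \
               --groups sim/labels.tsv --gmt sets.gmt --out ann/
k2tax benchmark --replicates 5 --out results.tsv
k2tax config --print-defaults
```

`run` writes `taxonomy.json` (canonical, byte-identical across reruns with
the same seed), `taxonomy.nwk` (branch lengths = height differences) and a
provenance block. Matrices are read from TSV/CSV (features × observations)
or MatrixMarket triplets (`matrix.mtx` + `features.tsv` + `barcodes.tsv`,
orientation auto-detected).

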