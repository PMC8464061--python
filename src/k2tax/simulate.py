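"""Synthetic expression data with an induced hierarchical structure.

The generator draws a random full binary tree over the terminal clusters,
splits the signal features round-robin over the internal branches, and at
each branch shifts the mean of its features by +/- effect_size on one
descendant side.  Observations are allocated near-evenly to terminal
clusters and iid Gaussian noise is added everywhere.  The default grid of
noise standard deviations (0.5-3.0) spans moderate to heavy noise relative
to the unit effect size.

The generator emulates block-structured log-expression with
branch-specific signal; it does not model count overdispersion, dropout,
library-size variation, or feature-feature correlation beyond the shared
branch shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix
from .taxonomy import Taxonomy, TaxonomyNode

__all__ = ["SimulationSpec", "simulate_hierarchy"]

NOISE_SD_GRID = (0.5, 1.0, 2.0, 3.0)


@dataclass
class SimulationSpec:
    """Parameters of one simulated data set.

    n_observations, n_features : matrix size
    n_terminal_clusters : leaves of the generating tree
    signal_fraction : fraction of features carrying a branch shift, in (0,1]
    noise_sd : sd of the iid Gaussian noise (log-expression units)
    effect_size : magnitude of each branch mean shift (default 1.0)
    group_mode : attach group labels equal to the terminal clusters
    """

    n_observations: int = 200
    n_features: int = 2000
    n_terminal_clusters: int = 4
    signal_fraction: float = 0.2
    noise_sd: float = 1.0
    effect_size: float = 1.0
    group_mode: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terminal_clusters < 2:
            raise ValueError("need >=2 terminal clusters")
        if self.n_terminal_clusters > self.n_observations:
            raise ValueError("more terminal clusters than observations")
        if not (0 < self.signal_fraction <= 1):
            raise ValueError("signal_fraction must be in (0, 1]")
        if self.noise_sd <= 0 or self.effect_size <= 0:
            raise ValueError("noise_sd and effect_size must be > 0")


def _random_tree(cluster_names: list[str], rng: np.random.Generator,
                 counter: list[int]) -> TaxonomyNode:
    nid = f"t{counter[0]}"
    counter[0] += 1
    node = TaxonomyNode(node_id=nid, member_items=list(cluster_names))
    n = len(cluster_names)
    if n == 1:
        return node
    # random binomial split, minority side >= n/4: a top-down K=2 procedure
    # can only identify hierarchies whose splits are locally dominant, and
    # a split hiding a single cluster behind a structured majority is not
    min_side = max(1, -(-n // 4))
    while True:
        k = int(rng.binomial(n, 0.5))
        if min(k, n - k) >= min_side:
            break
    node.children = [_random_tree(cluster_names[:k], rng, counter),
                     _random_tree(cluster_names[k:], rng, counter)]
    return node


def simulate_hierarchy(spec: SimulationSpec):
    """Generate (ExpressionMatrix, truth Taxonomy, labels) from a spec.

    Returns
    -------
    matrix : ExpressionMatrix (group labels attached when spec.group_mode)
    truth : Taxonomy over the terminal clusters (the generating tree)
    labels : list of terminal-cluster names, one per observation
    """
    rng = np.random.default_rng(spec.seed)
    c = spec.n_terminal_clusters
    names = [f"cluster{k}" for k in range(c)]
    shuffled = [names[i] for i in rng.permutation(c)]
    root = _random_tree(shuffled, rng, [0])

    def set_depth(node: TaxonomyNode, d: int) -> None:
        node.depth = d
        for ch in node.children:
            set_depth(ch, d + 1)

    set_depth(root, 1)
    truth = Taxonomy(root=root, mode="group", items=names)
    internal = [n for n in root.walk() if not n.is_leaf]

    n_signal = int(round(spec.signal_fraction * spec.n_features))
    if n_signal < len(internal):
        raise ValueError("insufficient signal features: "
                         f"{n_signal} signal features for {len(internal)} branches")
    signal_feats = rng.permutation(spec.n_features)[:n_signal]
    # features per branch proportional to the branch's leaf count, so higher
    # splits carry proportionally more signal and the induced distances
    # identify the generating tree (uniform allocation leaves unbalanced
    # trees ambiguous); every branch gets at least one feature
    weights = np.array([len(n.member_items) for n in internal], dtype=float)
    shares = weights / weights.sum() * n_signal
    counts = np.maximum(1, np.floor(shares).astype(int))
    while counts.sum() < n_signal:
        counts[np.argmax(shares - counts)] += 1
    while counts.sum() > n_signal:
        over = np.where(counts > 1)[0]
        counts[over[np.argmin((shares - counts)[over])]] -= 1
    bounds = np.cumsum(counts)[:-1]
    branch_feats = np.split(signal_feats, bounds)

    # near-even allocation of observations to clusters (remainder round-robin)
    base, rem = divmod(spec.n_observations, c)
    sizes = [base + (1 if k < rem else 0) for k in range(c)]
    labels: list[str] = []
    for k, sz in enumerate(sizes):
        labels.extend([names[k]] * sz)
    col_of_cluster = {nm: np.flatnonzero(np.array(labels) == nm) for nm in names}

    # each branch feature separates the branch's two sides by a +/-effect_size
    # pair of opposite shifts (which side gets + is random per feature); the
    # antisymmetric form keeps a branch's features variable across its whole
    # subtree, so the variability ranking of features matches the tree level
    means = np.zeros((spec.n_features, spec.n_observations))
    for node, feats in zip(internal, branch_feats):
        signs = rng.choice((-1.0, 1.0), size=len(feats))
        cols_l = np.concatenate([col_of_cluster[nm]
                                 for nm in node.children[0].member_items])
        cols_r = np.concatenate([col_of_cluster[nm]
                                 for nm in node.children[1].member_items])
        means[np.ix_(feats, cols_l)] += spec.effect_size * signs[:, None]
        means[np.ix_(feats, cols_r)] -= spec.effect_size * signs[:, None]

    values = means + rng.normal(0.0, spec.noise_sd, size=means.shape)
    obs_ids = [f"obs{i:04d}" for i in range(spec.n_observations)]
    feat_ids = [f"gene{j:05d}" for j in range(spec.n_features)]
    group_map = dict(zip(obs_ids, labels)) if spec.group_mode else None
    matrix = ExpressionMatrix(values, feat_ids, obs_ids, group_map)
    return matrix, truth, labels
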