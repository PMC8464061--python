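"""Tree-similarity and cluster-purity metrics.

Baker's gamma compares two hierarchies over the same leaves through the
rank correlation of their leaf-pairwise ancestor depths: for every pair of
leaves, the number of partitions from the root down to (and including)
their lowest common ancestor.  Conditional entropy measures how pure the
phenotype labels are inside a set of clusters.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import spearmanr

from .taxonomy import Taxonomy, TaxonomyNode

__all__ = ["bakers_gamma", "entropy", "lca_depths"]


def _leaf_items(node: TaxonomyNode) -> list[str]:
    return list(node.member_items)


def lca_depths(tree: Taxonomy) -> dict[tuple[str, str], int]:
    """Depth (partitions from root, inclusive) of the LCA of each item pair."""
    out: dict[tuple[str, str], int] = {}

    def pair_key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    for node in tree.root.walk():
        if node.is_leaf:
            for a, b in itertools.combinations(node.member_items, 2):
                out[pair_key(a, b)] = node.depth
        else:
            left, right = node.children
            for a in left.member_items:
                for b in right.member_items:
                    out[pair_key(a, b)] = node.depth
    return out


def bakers_gamma(tree_a: Taxonomy, tree_b: Taxonomy) -> float:
    """Spearman correlation of the two trees' pairwise LCA-depth vectors.

    Both trees must cover the identical leaf/item set.  Returns a value in
    [-1, 1]; 1 for structurally identical trees.  If either depth vector is
    constant (no rank variation, e.g. two leaves), returns 1.0 when the
    vectors coincide and 0.0 otherwise.
    """
    items_a = sorted(tree_a.root.member_items)
    items_b = sorted(tree_b.root.member_items)
    if items_a != items_b:
        raise ValueError("trees have different leaf sets")
    da = lca_depths(tree_a)
    db = lca_depths(tree_b)
    pairs = sorted(da)
    va = np.array([da[p] for p in pairs], dtype=float)
    vb = np.array([db[p] for p in pairs], dtype=float)
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return 1.0 if np.array_equal(va, vb) else 0.0
    rho = spearmanr(va, vb).statistic
    return float(rho)


def entropy(labels, clusters) -> float:
    """Size-weighted conditional Shannon entropy (bits) of labels in clusters.

    ``labels`` maps observation -> label (or is a sequence parallel to the
    union of cluster members); ``clusters`` is an iterable of observation
    collections.  0 iff every cluster is label-pure.
    """
    if not isinstance(labels, dict):
        raise TypeError("labels must be a dict observation -> label")
    total = sum(len(c) for c in clusters)
    if total == 0:
        raise ValueError("empty clustering")
    h = 0.0
    for members in clusters:
        if len(members) == 0:
            continue
        vals, counts = np.unique([labels[m] for m in members], return_counts=True)
        p = counts / counts.sum()
        hc = float(-(p * np.log2(p)).sum())
        h += (len(members) / total) * hc
    return h
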