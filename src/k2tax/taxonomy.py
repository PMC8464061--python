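"""Recursive taxonomy construction and the resulting tree structure.

The driver applies the ensemble K=2 partition at the root item set and
recurses into each side until a stopping rule fires: too few items, a
partition stability below the configured minimum, or a degenerate ensemble.
Each split re-runs feature selection inside its own item subset, so every
level of the hierarchy is driven by its own discriminatory features.

Branch heights follow the stability heuristic

    h_m = log(N_m) + sum_{l=1..m} log(PS_l) + c

with the sum over the partitions from the root down to (and including) the
node's own, and c the per-tree constant that places the minimum internal
node height at exactly 1.  Terminal leaves hang at half their parent's
height (the height formula only covers partition nodes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np

from .matrix import ExpressionMatrix
from .partition import (LINKAGES, UnsplittableError, aggregate_partition,
                        build_ensemble, cosine_similarity, partition_stability)

__all__ = ["RunConfig", "TaxonomyNode", "Taxonomy", "run_taxonomy",
           "compute_heights", "cut_tree", "taxonomy_from_linkage"]

import logging

log = logging.getLogger("k2tax")

_SELECT_METHODS = ("mad", "sd", "f")


@dataclass
class RunConfig:
    """All knobs of a taxonomy run; the seed fully determines the output.

    mode : "observation" | "group"
    p : perturbations per node (default 100; the stability's standard error
        shrinks as 1/sqrt(p))
    feature_select : "sd" | "mad" | "f" (F requires group labels)
    n_features : "sqrt" (round(sqrt(F))) or an explicit integer
    perturbation_linkage : ward|average|complete|single (default ward) for
        the perturbation-specific observation clustering
    aggregate_linkage : same choices (default average -- the consensus-matrix
        convention: the cut follows mean ensemble similarity, so a majority
        bipartition of the perturbations is never outvoted by a minority
        one, which a variance-based update can do)
    stability_min : stop splitting when PS falls below this (0 = never)
    min_items : smallest item set still split (default 3 observation mode,
        2 group mode)
    custom_partitioner : optional callable(selected_values, item_ids, seed)
        -> +/-1 vector with one entry per item, plugged in place of the
        built-in perturbation partitioner (selected_values is the
        bootstrapped, feature-selected k x n_observations array)
    """

    mode: str = "observation"
    p: int = 100
    feature_select: str = "sd"
    n_features: str | int = "sqrt"
    perturbation_linkage: str = "ward"
    aggregate_linkage: str = "average"
    stability_min: float = 0.0
    min_items: Optional[int] = None
    seed: int = 42
    custom_partitioner: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.mode not in ("observation", "group"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.feature_select.lower() not in _SELECT_METHODS:
            raise ValueError(f"unknown feature_select {self.feature_select!r}")
        self.feature_select = self.feature_select.lower()
        for lk in (self.perturbation_linkage, self.aggregate_linkage):
            if lk not in LINKAGES:
                raise ValueError(f"unknown linkage {lk!r}")
        if not (0.0 <= self.stability_min < 1.0):
            raise ValueError("stability_min must be in [0, 1)")
        if self.min_items is None:
            self.min_items = 3 if self.mode == "observation" else 2
        if self.min_items < 2:
            raise ValueError("min_items must be >= 2")
        self.seed = int(self.seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("custom_partitioner")
        return d


@dataclass
class TaxonomyNode:
    node_id: str
    member_items: list[str]
    children: list["TaxonomyNode"] = field(default_factory=list)
    PS: Optional[float] = None
    depth: int = 1                      # 1-based level; root = 1
    height: Optional[float] = None
    stop_reason: Optional[str] = None   # set on leaves

    @property
    def N_m(self) -> int:
        return len(self.member_items)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class Taxonomy:
    """Binary tree of partitions over all items of a run."""

    root: TaxonomyNode
    mode: str = "observation"
    items: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def nodes(self) -> list[TaxonomyNode]:
        return list(self.root.walk())

    def internal_nodes(self) -> list[TaxonomyNode]:
        return [n for n in self.root.walk() if not n.is_leaf]

    def leaves(self) -> list[TaxonomyNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def node(self, node_id: str) -> TaxonomyNode:
        for n in self.root.walk():
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        nodes = []
        for n in self.root.walk():
            nodes.append({
                "node_id": n.node_id,
                "member_items": list(n.member_items),
                "children": [c.node_id for c in n.children],
                "PS": n.PS,
                "N_m": n.N_m,
                "depth": n.depth,
                "height": n.height,
                "stop_reason": n.stop_reason,
            })
        return {"mode": self.mode, "items": list(self.items),
                "config": dict(self.config), "nodes": nodes}

    @classmethod
    def from_dict(cls, d: dict) -> "Taxonomy":
        by_id = {}
        for rec in d["nodes"]:
            by_id[rec["node_id"]] = TaxonomyNode(
                node_id=rec["node_id"], member_items=list(rec["member_items"]),
                PS=rec["PS"], depth=rec["depth"], height=rec["height"],
                stop_reason=rec["stop_reason"])
        for rec in d["nodes"]:
            by_id[rec["node_id"]].children = [by_id[c] for c in rec["children"]]
        root = by_id[d["nodes"][0]["node_id"]]
        return cls(root=root, mode=d["mode"], items=list(d["items"]),
                   config=dict(d.get("config", {})))


# ----------------------------------------------------------------------

def _member_observations(matrix: ExpressionMatrix, mode: str,
                         items: list[str]) -> list[str]:
    if mode == "observation":
        return list(items)
    keep = set(items)
    return [o for o in matrix.observation_ids if matrix.group_labels[o] in keep]


def run_taxonomy(matrix: ExpressionMatrix, config: RunConfig) -> Taxonomy:
    """Depth-first recursive ensemble partitioning of the full item set."""
    if config.mode == "group":
        if matrix.group_labels is None:
            raise ValueError("group mode requires group labels")
        items = list(matrix.groups())
    else:
        items = list(matrix.observation_ids)
    if len(items) < 2:
        raise ValueError("need >=2 items overall")

    counter = [0]

    def next_id() -> str:
        nid = f"n{counter[0]}"
        counter[0] += 1
        return nid

    def grow(members: list[str], depth: int) -> TaxonomyNode:
        node = TaxonomyNode(node_id=next_id(), member_items=list(members), depth=depth)
        if len(members) < config.min_items:
            node.stop_reason = "min_items"
            return node
        sub = matrix.subset_observations(_member_observations(matrix, config.mode, members))
        try:
            ens = build_ensemble(sub, members, config)
        except UnsplittableError as exc:
            node.stop_reason = f"degenerate: {exc}"
            log.info("node %s N=%d leaf (%s)", node.node_id, len(members), node.stop_reason)
            return node
        q = cosine_similarity(ens)
        ps = partition_stability(q)
        node.PS = ps
        if ps < config.stability_min:
            node.stop_reason = "stability"
            log.info("node %s N=%d PS=%.4f leaf (below stability_min)",
                     node.node_id, len(members), ps)
            return node
        if ps <= 0.0:
            node.stop_reason = "zero-stability"
            log.info("node %s N=%d PS=0 leaf", node.node_id, len(members))
            return node
        split = aggregate_partition(q, config.aggregate_linkage)
        side_a = [m for m, s in zip(members, split) if s == split[0]]
        side_b = [m for m, s in zip(members, split) if s != split[0]]
        log.info("node %s N=%d PS=%.4f split %d|%d",
                 node.node_id, len(members), ps, len(side_a), len(side_b))
        node.children = [grow(side_a, depth + 1), grow(side_b, depth + 1)]
        return node

    root = grow(items, 1)
    tax = Taxonomy(root=root, mode=config.mode, items=items, config=config.to_dict())
    compute_heights(tax)
    return tax


def compute_heights(taxonomy: Taxonomy) -> Taxonomy:
    """Assign h_m to every node (in place); min internal height is exactly 1."""
    raw: dict[str, float] = {}

    def walk(node: TaxonomyNode, log_ps_sum: float) -> None:
        if node.is_leaf:
            return
        if node.PS is None or node.PS <= 0:
            raise ValueError(f"internal node {node.node_id} has PS <= 0")
        s = log_ps_sum + math.log(node.PS)
        raw[node.node_id] = math.log(node.N_m) + s
        for c in node.children:
            walk(c, s)

    walk(taxonomy.root, 0.0)
    if not raw:
        taxonomy.root.height = 1.0
        return taxonomy
    c = 1.0 - min(raw.values())

    def assign(node: TaxonomyNode, parent_h: Optional[float]) -> None:
        if node.is_leaf:
            node.height = 1.0 if parent_h is None else 0.5 * parent_h
        else:
            node.height = raw[node.node_id] + c
            if parent_h is not None and not node.height < parent_h:
                raise ValueError("height monotonicity violated")
        for ch in node.children:
            assign(ch, node.height)

    assign(taxonomy.root, None)
    return taxonomy


def cut_tree(taxonomy: Taxonomy, K: int) -> list[list[str]]:
    """K mutually exclusive item clusters by opening nodes in height order."""
    n_leaves = len(taxonomy.leaves())
    if K < 2 or K > n_leaves:
        raise ValueError(f"K must be in [2, {n_leaves}]")
    frontier = [taxonomy.root]
    while len(frontier) < K:
        openable = [n for n in frontier if not n.is_leaf]
        openable.sort(key=lambda n: (-(n.height if n.height is not None else 0.0),
                                     n.node_id))
        top = openable[0]
        i = frontier.index(top)
        frontier[i:i + 1] = top.children
    return [list(n.member_items) for n in frontier]


def taxonomy_from_linkage(z: np.ndarray, leaf_ids: list[str]) -> Taxonomy:
    """Wrap a scipy linkage matrix as a Taxonomy (for baselines/metrics)."""
    z = np.asarray(z)
    n = len(leaf_ids)
    nodes: dict[int, TaxonomyNode] = {
        i: TaxonomyNode(node_id=f"leaf_{leaf_ids[i]}", member_items=[leaf_ids[i]])
        for i in range(n)}
    for r in range(z.shape[0]):
        a, b = int(z[r, 0]), int(z[r, 1])
        child_a, child_b = nodes[a], nodes[b]
        nodes[n + r] = TaxonomyNode(
            node_id=f"m{r}",
            member_items=child_a.member_items + child_b.member_items,
            children=[child_a, child_b], height=float(z[r, 2]))
    root = nodes[n + z.shape[0] - 1]

    def depths(node: TaxonomyNode, d: int) -> None:
        node.depth = d
        for ch in node.children:
            depths(ch, d + 1)

    depths(root, 1)
    return Taxonomy(root=root, mode="observation", items=list(leaf_ids))
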