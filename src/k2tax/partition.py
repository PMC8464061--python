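"""Ensemble K=2 partition estimation for one node of the taxonomy.

For each of p perturbations: bootstrap the features, select the most
variable ones, and run a K=2 clustering -- Ward (or another linkage) on
Euclidean distances for observation-level items, constrained k-means for
group-level items.  The p dichotomous assignments are aggregated into an
N x N cosine-similarity matrix Q (the Hamann similarity of the +/-1
assignment vectors, identical to the Pearson correlation of their
standardized forms), from which the aggregate split and a closed-form
stability statistic are computed.

Partition stability::

    PS = max_k (v_k - k/N),    v_k = (sum_{l<=k} lambda_l) / N

with lambda the descending eigenvalues of Q.  PS is 0 when assignments are
random (Q ~ identity) and 1 - 1/N when every perturbation induces the same
bipartition (Q is +/-1 rank-one).

The constrained k-means of group-level mode is realized as k-means over
group centroids weighted by group size.  For complete must-link blocks the
two are equivalent: the cost of assigning a block to a centroid decomposes
as size * dist(block centroid, centroid)^2 + a constant, so the weighted
centroid problem has the same argmin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from ._rng import child_int_seed, child_rng, node_key
from .features import bootstrap_indices, feature_statistic, n_selected
from .matrix import ExpressionMatrix

__all__ = [
    "AssignmentEnsemble", "CosineMatrix", "UnsplittableError",
    "perturb_partition_observation", "perturb_partition_group",
    "build_ensemble", "cosine_similarity", "partition_stability",
    "aggregate_partition",
]

log = logging.getLogger("k2tax")

LINKAGES = ("ward", "average", "complete", "single")
MAX_RESAMPLE_ATTEMPTS = 10


class UnsplittableError(RuntimeError):
    """A perturbation whose selected features cannot separate the items."""


@dataclass
class AssignmentEnsemble:
    """The p perturbation-specific dichotomous assignments of N items."""

    item_ids: list[str]
    assignments: np.ndarray          # N x p, entries in {-1, +1}
    per_perturbation_seed: list[int] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments)
        if a.ndim != 2 or a.shape[0] != len(self.item_ids):
            raise ValueError("assignments must be N x p")
        if a.shape[1] < 1:
            raise ValueError("ensemble needs p >= 1 perturbations")
        if not np.all(np.isin(a, (-1, 1))):
            raise ValueError("assignments must be +/-1")
        if np.any(np.all(a == a[0, :], axis=0)):
            raise ValueError("every perturbation column must contain both labels")
        self.assignments = a.astype(np.int8)

    @property
    def p(self) -> int:
        return self.assignments.shape[1]


@dataclass
class CosineMatrix:
    """Item-by-item cosine similarities with eigendecomposition artifacts."""

    Q: np.ndarray
    eigenvalues: np.ndarray | None = None   # descending
    cum_var: np.ndarray | None = None       # v_k
    stability: float | None = None          # PS

    @property
    def n(self) -> int:
        return self.Q.shape[0]


# ----------------------------------------------------------------------
# perturbation-specific K=2 partitions
# ----------------------------------------------------------------------

def _signed(labels: np.ndarray) -> np.ndarray:
    """Map the two cluster labels to +/-1 (first item's cluster -> +1)."""
    out = np.where(labels == labels[0], 1, -1).astype(np.int8)
    return out


def _cut_two(values_cols: np.ndarray, method: str) -> np.ndarray:
    """K=2 tree cut of agglomerative clustering of the columns."""
    d = pdist(values_cols.T, metric="euclidean")
    if np.all(d == 0):
        raise UnsplittableError("all pairwise distances are zero")
    z = scipy_linkage(d, method=method)
    labels = fcluster(z, t=2, criterion="maxclust")
    if len(np.unique(labels)) < 2:
        raise UnsplittableError("tree cut produced a single cluster")
    return _signed(labels)


def perturb_partition_observation(matrix: ExpressionMatrix,
                                  linkage: str = "ward") -> np.ndarray:
    """One +/-1 assignment of the observations (already bootstrapped+selected).

    Euclidean distances over the matrix rows, agglomerative clustering with
    the given linkage, K=2 cut.  The +/-1 sign is arbitrary; the downstream
    cosine matrix is invariant to per-perturbation sign flips.
    """
    if matrix.n_observations < 2:
        raise ValueError("need >=2 observations to split")
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    return _cut_two(matrix.values, linkage)


def _weighted_two_means(centroids: np.ndarray, weights: np.ndarray,
                        seed: int) -> np.ndarray:
    """Size-weighted K=2 k-means over group centroids (rows)."""
    g = centroids.shape[0]
    if g == 2:
        return np.array([1, -1], dtype=np.int8)
    if np.all(np.ptp(centroids, axis=0) == 0):
        raise UnsplittableError("all group centroids identical")
    km = KMeans(n_clusters=2, n_init=10, max_iter=300, tol=1e-6,
                random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ConvergenceWarning -> best-so-far
        labels = km.fit_predict(centroids, sample_weight=weights)
    if len(np.unique(labels)) < 2:
        raise UnsplittableError("k-means collapsed to a single cluster")
    return _signed(labels)


def perturb_partition_group(matrix: ExpressionMatrix,
                            group_labels: dict[str, str] | None = None,
                            seed: int = 0) -> np.ndarray:
    """One +/-1 assignment per group via constrained (must-link) K=2 k-means.

    All observations of a group are must-linked, which reduces exactly to
    size-weighted k-means over group centroids.  Returns one label per
    group in first-appearance order of the groups.
    """
    labels = group_labels if group_labels is not None else matrix.group_labels
    if labels is None:
        raise ValueError("group labels required")
    groups: dict[str, list[int]] = {}
    for j, o in enumerate(matrix.observation_ids):
        groups.setdefault(labels[o], []).append(j)
    if len(groups) < 2:
        raise ValueError("need >=2 groups to split")
    for g, cols in groups.items():
        if len(cols) == 0:
            raise ValueError(f"group {g!r} has no observations")
    cents = np.stack([matrix.values[:, cols].mean(axis=1) for cols in groups.values()])
    sizes = np.array([len(cols) for cols in groups.values()], dtype=float)
    return _weighted_two_means(cents, sizes, seed)


# ----------------------------------------------------------------------
# ensemble construction
# ----------------------------------------------------------------------

def build_ensemble(matrix: ExpressionMatrix, items: list[str], config) -> AssignmentEnsemble:
    """The p-column assignment ensemble at one node.

    ``items`` are observation ids (observation mode) or group names (group
    mode); the matrix must already be restricted to the node's observations.
    Perturbations whose bootstrap yields no separating features are
    resampled up to 10 times and then dropped; a node losing more than half
    its perturbations raises UnsplittableError (the caller stops the node).
    """
    mode = config.mode
    if mode == "group":
        groups = matrix.groups()
        if set(groups) != set(items):
            raise ValueError("items do not match the matrix's groups")
        item_ids = list(items)
        codes = np.array([item_ids.index(matrix.group_labels[o])
                          for o in matrix.observation_ids])
        # indicator for fast centroid computation
        ind = np.zeros((matrix.n_observations, len(item_ids)))
        ind[np.arange(matrix.n_observations), codes] = 1.0
        sizes = ind.sum(axis=0)
        if np.any(sizes == 0):
            raise ValueError("a group has zero observations at this node")
    else:
        item_ids = list(items)
        if item_ids != matrix.observation_ids:
            raise ValueError("items must equal the matrix's observations")
        codes = None
    n_items = len(item_ids)
    if n_items < 2:
        raise ValueError("need >=2 items at a node")

    key = node_key(item_ids)
    k = n_selected(matrix.n_features, config.n_features)
    values = matrix.values
    f_codes = codes if config.feature_select.lower() == "f" else None

    columns: list[np.ndarray] = []
    seeds: list[int] = []
    dropped = 0
    for b in range(config.p):
        col = None
        for attempt in range(MAX_RESAMPLE_ATTEMPTS + 1):
            rng = child_rng(config.seed, key, b, attempt)
            idx = bootstrap_indices(matrix.n_features, rng)
            boot = values[idx, :]
            stat = feature_statistic(boot, config.feature_select, f_codes)
            if np.all(stat == 0):
                continue
            sel = boot[np.argsort(-stat, kind="stable")[:k], :]
            try:
                if getattr(config, "custom_partitioner", None) is not None:
                    col = np.asarray(config.custom_partitioner(
                        sel, item_ids, child_int_seed(config.seed, key, b, attempt, 2)),
                        dtype=np.int8)
                    if col.shape != (n_items,) or not np.all(np.isin(col, (-1, 1))) \
                            or len(np.unique(col)) < 2:
                        raise UnsplittableError("custom partitioner returned no split")
                elif mode == "group":
                    cents = (sel @ ind) / sizes
                    col = _weighted_two_means(cents.T, sizes,
                                              child_int_seed(config.seed, key, b, attempt, 1))
                else:
                    col = _cut_two(sel, config.perturbation_linkage)
            except UnsplittableError:
                continue
            seeds.append(child_int_seed(config.seed, key, b, attempt))
            break
        if col is None:
            dropped += 1
        else:
            columns.append(col)
    if dropped > config.p / 2:
        raise UnsplittableError(
            f"degenerate node: {dropped}/{config.p} perturbations unsplittable")
    if not columns:
        raise UnsplittableError("degenerate node: no splittable perturbation")
    return AssignmentEnsemble(item_ids, np.stack(columns, axis=1), seeds, dropped)


# ----------------------------------------------------------------------
# cosine matrix, stability, aggregate split
# ----------------------------------------------------------------------

def cosine_similarity(ensemble: AssignmentEnsemble) -> CosineMatrix:
    """Pairwise cosine similarities Q_ij = (X_i . X_j)/p of the +/-1 rows.

    Equals the Hamann similarity (matches - mismatches)/p and the Pearson
    correlation of the standardized rows.
    """
    a = ensemble.assignments.astype(float)
    q = (a @ a.T) / ensemble.p
    np.fill_diagonal(q, 1.0)
    return CosineMatrix(Q=q)


def _as_q(q) -> np.ndarray:
    if isinstance(q, CosineMatrix):
        q = q.Q
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] != q.shape[1]:
        raise ValueError("Q must be square")
    if q.shape[0] < 2:
        raise ValueError("Q must be at least 2 x 2")
    if np.max(np.abs(q - q.T)) > 1e-8:
        raise ValueError("Q is not symmetric")
    return q


def partition_stability(q) -> float:
    """PS = max_k (v_k - k/N) from the eigendecomposition of Q.

    Eigenvalues are sorted descending; values within 1e-10 of zero are
    clipped to zero before the cumulative sums; negative eigenvalues (a
    numerical possibility) are retained.
    """
    qm = _as_q(q)
    n = qm.shape[0]
    lam = np.linalg.eigvalsh(qm)[::-1]
    lam = np.where(np.abs(lam) < 1e-10, 0.0, lam)
    v = np.cumsum(lam) / n
    ks = np.arange(1, n + 1)
    ps = float(np.max(v - ks / n))
    ps = max(ps, 0.0)
    if isinstance(q, CosineMatrix):
        q.eigenvalues = lam
        q.cum_var = v
        q.stability = ps
    return ps


def aggregate_partition(q, linkage: str = "ward") -> np.ndarray:
    """Aggregate K=2 split: cluster the distance matrix D = 1 - Q.

    Returns one +/-1 label per item (first item -> +1); both sides are
    always nonempty.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}")
    qm = _as_q(q)
    d = 1.0 - qm
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    z = scipy_linkage(squareform(d, checks=False), method=linkage)
    labels = fcluster(z, t=2, criterion="maxclust")
    if len(np.unique(labels)) < 2:
        # exact ties everywhere; force a split of the first leaf merge
        labels = np.ones(qm.shape[0], dtype=int)
        labels[0] = 2
    return _signed(labels)
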