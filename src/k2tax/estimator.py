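"""Scikit-learn style estimator facade over the taxonomy engine."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .matrix import ExpressionMatrix
from .taxonomy import RunConfig, cut_tree, run_taxonomy

__all__ = ["K2Taxonomer"]


class K2Taxonomer(ClusterMixin, BaseEstimator):
    """Ensemble recursive K=2 partitioning of samples or sample groups.

    Builds a binary "taxonomy-like" hierarchy over the samples (or, when
    ``groups`` is passed to :meth:`fit`, over pre-labeled sample groups such
    as single-cell clusters).  Each split is estimated from an ensemble of
    feature-bootstrapped, feature-selected K=2 clusterings, aggregated
    through a cosine-similarity matrix whose eigendecomposition yields a
    per-partition stability score.

    Parameters
    ----------
    n_perturbations : int, default=100
        Ensemble size p per partition.
    feature_select : {"sd", "mad", "f"}, default="sd"
        Variability statistic for per-partition feature selection ("f"
        requires group-level fitting).
    n_features : "sqrt" or int, default="sqrt"
        Features kept per perturbation; "sqrt" keeps round(sqrt(F)).
    perturbation_linkage, aggregate_linkage : {"ward","average","complete","single"}
        Agglomeration methods for the perturbation-specific clustering
        (observation mode; default "ward") and for the aggregate
        cosine-distance clustering (default "average", the consensus-matrix
        convention).
    stability_min : float, default=0.0
        Stop splitting when the partition stability PS falls below this.
    min_items : int or None
        Smallest item set still split (None: 3 for samples, 2 for groups).
    n_clusters : int or None
        If set, ``labels_`` holds the ``n_clusters``-way tree cut;
        otherwise each terminal leaf is one cluster.
    random_state : int, default=42
        Master seed; fully determines the fitted taxonomy.

    Attributes
    ----------
    taxonomy_ : Taxonomy
        The fitted binary hierarchy (per-node members, PS, heights).
    labels_ : ndarray of shape (n_samples,)
        Cluster index per sample (see ``n_clusters``).
    stability_ : float
        PS of the root partition (nan if the root was not split).

    Examples
    --------
    >>> import numpy as np
    >>> from k2tax import K2Taxonomer
    >>> rng = np.random.default_rng(0)
    >>> X = np.vstack([rng.normal(m, 0.3, (10, 50)) for m in (0, 3)])
    >>> est = K2Taxonomer(n_perturbations=25, random_state=0).fit(X)
    >>> est.stability_  # doctest: +SKIP
    0.49
    """

    def __init__(self, n_perturbations: int = 100, feature_select: str = "sd",
                 n_features="sqrt", perturbation_linkage: str = "ward",
                 aggregate_linkage: str = "average", stability_min: float = 0.0,
                 min_items=None, n_clusters=None, random_state: int = 42):
        self.n_perturbations = n_perturbations
        self.feature_select = feature_select
        self.n_features = n_features
        self.perturbation_linkage = perturbation_linkage
        self.aggregate_linkage = aggregate_linkage
        self.stability_min = stability_min
        self.min_items = min_items
        self.n_clusters = n_clusters
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self, mode: str) -> RunConfig:
        return RunConfig(mode=mode, p=self.n_perturbations,
                         feature_select=self.feature_select,
                         n_features=self.n_features,
                         perturbation_linkage=self.perturbation_linkage,
                         aggregate_linkage=self.aggregate_linkage,
                         stability_min=self.stability_min,
                         min_items=self.min_items,
                         seed=self.random_state if self.random_state is not None else 0)

    def fit(self, X, y=None, groups=None):
        """Fit the taxonomy on X of shape (n_samples, n_features).

        ``groups`` (array-like of n_samples labels) switches to group-level
        mode: the taxonomy is built over the groups, with every sample
        must-linked to its group.
        """
        if isinstance(X, pd.DataFrame):
            obs_ids = [str(i) for i in X.index]
            feat_ids = [str(c) for c in X.columns]
            self.feature_names_in_ = np.asarray(feat_ids, dtype=object)
            values = check_array(X.to_numpy(dtype=float))
        else:
            values = check_array(X, dtype=float)
            obs_ids = [f"obs{i}" for i in range(values.shape[0])]
            feat_ids = [f"f{j}" for j in range(values.shape[1])]
        self.n_features_in_ = values.shape[1]

        group_map = None
        mode = "observation"
        if groups is not None:
            groups = np.asarray(groups)
            if groups.shape[0] != values.shape[0]:
                raise ValueError("groups must have one label per sample")
            group_map = {o: str(g) for o, g in zip(obs_ids, groups)}
            mode = "group"
        matrix = ExpressionMatrix(values.T, feat_ids, obs_ids, group_map)
        self.taxonomy_ = run_taxonomy(matrix, self._config(mode))
        root = self.taxonomy_.root
        self.stability_ = float(root.PS) if root.PS is not None else float("nan")
        self.observation_ids_ = obs_ids
        self._group_map = group_map
        if self.n_clusters is not None:
            self.labels_ = self.cut(self.n_clusters)
        else:
            clusters = [leaf.member_items for leaf in self.taxonomy_.leaves()]
            self.labels_ = self._labels_from_item_clusters(clusters)
        return self

    # ------------------------------------------------------------------
    def _labels_from_item_clusters(self, clusters) -> np.ndarray:
        item_to_cluster = {it: k for k, members in enumerate(clusters) for it in members}
        if self._group_map is None:
            return np.array([item_to_cluster[o] for o in self.observation_ids_])
        return np.array([item_to_cluster[self._group_map[o]]
                         for o in self.observation_ids_])

    def cut(self, K: int) -> np.ndarray:
        """K-way tree cut; returns one cluster index per fitted sample."""
        check_is_fitted(self, "taxonomy_")
        return self._labels_from_item_clusters(cut_tree(self.taxonomy_, K))
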