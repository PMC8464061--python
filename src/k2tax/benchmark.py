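"""Simulation benchmark: ensemble taxonomy vs Ward agglomeration.

For each grid cell (noise sd x number of terminal clusters) the generator
produces replicate data sets; the ensemble method runs in group-level mode
on the true terminal-cluster labels, while the Ward baseline clusters the
per-group mean profiles (all features).  Recovery of the generating tree
is scored with Baker's gamma and the paired per-cell difference is tested
with the Wilcoxon signed-rank test, BH-corrected across cells.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist
from scipy.stats import wilcoxon

from ._rng import child_int_seed
from .annotation import fdr_adjust
from .matrix import ExpressionMatrix
from .metrics import bakers_gamma
from .simulate import SimulationSpec, simulate_hierarchy
from .taxonomy import RunConfig, run_taxonomy, taxonomy_from_linkage

__all__ = ["benchmark", "ward_group_means_taxonomy"]

log = logging.getLogger("k2tax")


def ward_group_means_taxonomy(matrix: ExpressionMatrix):
    """Ward agglomeration of per-group mean profiles (the classical baseline)."""
    groups = matrix.groups()
    names = list(groups)
    idx = {o: j for j, o in enumerate(matrix.observation_ids)}
    means = np.stack([matrix.values[:, [idx[o] for o in obs]].mean(axis=1)
                      for obs in groups.values()])
    z = scipy_linkage(pdist(means, metric="euclidean"), method="ward")
    return taxonomy_from_linkage(z, names)


def _one_cell(noise_sd: float, n_clusters: int, replicates: int, *,
              n_observations: int, n_features: int, signal_fraction: float,
              effect_size: float, p: int, seed: int, feature_select: str,
              methods: tuple[str, ...]) -> list[dict]:
    rows = []
    for r in range(replicates):
        spec = SimulationSpec(
            n_observations=n_observations, n_features=n_features,
            n_terminal_clusters=n_clusters, signal_fraction=signal_fraction,
            noise_sd=noise_sd, effect_size=effect_size, group_mode=True,
            seed=child_int_seed(seed, int(noise_sd * 1000), n_clusters, r))
        matrix, truth, _ = simulate_hierarchy(spec)
        for method in methods:
            try:
                if method == "k2tax":
                    cfg = RunConfig(mode="group", p=p,
                                    feature_select=feature_select,
                                    seed=child_int_seed(spec.seed, 7))
                    tax = run_taxonomy(matrix, cfg)
                elif method == "ward":
                    tax = ward_group_means_taxonomy(matrix)
                else:
                    raise ValueError(f"unknown method {method!r}")
                gamma = bakers_gamma(tax, truth)
            except Exception as exc:   # a failed replicate is recorded, not fatal
                log.warning("benchmark %s failed (sd=%s, c=%s, rep=%s): %s",
                            method, noise_sd, n_clusters, r, exc)
                gamma = np.nan
            rows.append({"noise_sd": noise_sd, "n_clusters": n_clusters,
                         "replicate": r, "method": method, "bakers_gamma": gamma})
    return rows


def benchmark(noise_sds=(0.5, 1.0, 2.0), n_clusters_list=(4, 8), replicates: int = 5,
              *, n_observations: int = 200, n_features: int = 2000,
              signal_fraction: float = 0.2, effect_size: float = 1.0,
              p: int = 100, seed: int = 0, feature_select: str = "f",
              methods: tuple[str, ...] = ("k2tax", "ward")):
    """Run the grid; returns (per-replicate results, per-cell summary).

    Group-level runs use F-statistic feature selection by default (the
    group-level convention: the between/within variance ratio exploits the
    known labels).  The summary holds each method's mean Baker's gamma per
    cell plus the paired Wilcoxon signed-rank p (methods[0] vs methods[1])
    and its BH q.  Cells with fewer than 3 paired values are excluded from
    the test.
    """
    if replicates < 3:
        raise ValueError("need >=3 replicates")
    self_compare = len(methods) >= 2 and methods[0] == methods[1]
    if self_compare:
        methods = (methods[0],)
    rows: list[dict] = []
    for sd in noise_sds:
        for c in n_clusters_list:
            rows.extend(_one_cell(
                sd, c, replicates, n_observations=n_observations,
                n_features=n_features, signal_fraction=signal_fraction,
                effect_size=effect_size, p=p, seed=seed,
                feature_select=feature_select, methods=methods))
    results = pd.DataFrame(rows)

    summary_rows = []
    for (sd, c), cell in results.groupby(["noise_sd", "n_clusters"]):
        rec: dict = {"noise_sd": sd, "n_clusters": c}
        pivot = cell.pivot(index="replicate", columns="method", values="bakers_gamma")
        for m in methods:
            rec[f"mean_gamma_{m}"] = float(pivot[m].mean()) if m in pivot else np.nan
        pval = np.nan
        if self_compare:
            # a method paired with itself: every difference is zero
            pval = 1.0 if pivot[methods[0]].notna().sum() >= 3 else np.nan
        elif len(methods) >= 2 and all(m in pivot for m in methods[:2]):
            paired = pivot[list(methods[:2])].dropna()
            if len(paired) >= 3:
                diff = paired.iloc[:, 0] - paired.iloc[:, 1]
                if np.allclose(diff, 0):
                    pval = 1.0
                else:
                    pval = float(wilcoxon(diff).pvalue)
        rec["wilcoxon_p"] = pval
        summary_rows.append(rec)
    summary = pd.DataFrame(summary_rows)
    if summary["wilcoxon_p"].notna().any():
        summary["wilcoxon_q"] = fdr_adjust(summary["wilcoxon_p"].to_numpy())
    else:
        summary["wilcoxon_q"] = np.nan
    return results, summary
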