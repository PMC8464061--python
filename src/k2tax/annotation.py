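"""Statistical characterization of taxonomy subgroups.

Per partition (the two subgroups at one internal node) the suite provides:

* differential expression with empirical-Bayes variance moderation -- the
  per-feature residual variances are shrunk toward a prior fitted by
  moments on the log variances, and the moderated t gets the prior degrees
  of freedom added to its null distribution;
* compact up-regulated gene signatures (FDR, expression and size caps);
* gene-set over-representation via the one-sided hypergeometric test;
* single-sample gene-set projection scores -- a rank-based statistic,
  invariant to any monotone transform of an observation's profile -- and
  their partition-level differential analysis;
* phenotype association tests (t / Wilcoxon rank-sum for continuous,
  Fisher's exact for categorical variables).

All p-values within one analysis are Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, gammaln, polygamma
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "SignatureRule", "fdr_adjust", "differential_expression",
    "derive_signature", "hypergeometric_enrichment", "project_gene_sets",
    "phenotype_tests", "annotate_taxonomy", "read_gmt_dict",
]

log = logging.getLogger("k2tax")


@dataclass
class SignatureRule:
    """Thresholds for deriving a subgroup signature.

    fdr_max : keep features with q below this (default 1e-10)
    min_mean : minimum mean expression in the subgroup itself, log2 scale
        (default 0.5)
    max_genes : signature size cap (default 50)
    """

    fdr_max: float = 1e-10
    min_mean: float = 0.5
    max_genes: int = 50

    def __post_init__(self) -> None:
        if self.max_genes < 1:
            raise ValueError("max_genes must be >= 1")


# ----------------------------------------------------------------------
# FDR
# ----------------------------------------------------------------------

def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN inputs stay NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        if (~ok).sum():
            log.warning("fdr_adjust: dropped %d NaN p-values", int((~ok).sum()))
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ----------------------------------------------------------------------
# moderated t
# ----------------------------------------------------------------------

def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if np.max(np.abs(dif / x)) < 1e-10:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of the scaled inverse-chi-square variance prior.

    Returns (prior df d0, prior variance s0^2); d0 may be inf when the
    observed log-variances are underdispersed relative to chi-square.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 2:
        return np.inf, float(s2[pos].mean()) if pos.any() else 0.0
    z = np.log(s2[pos])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (len(e) - 1) - polygamma(1, df / 2.0)
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # underdispersed log-variances: infinite prior df, common variance
        d0 = np.inf
        s02 = float(s2[pos].mean())
    return d0, s02


def differential_expression(matrix: ExpressionMatrix,
                            partition: tuple[list[str], list[str]],
                            moderated: bool = True) -> pd.DataFrame:
    """Two-subgroup differential expression at one partition.

    ``partition`` is (side_a observation ids, side_b observation ids); the
    effect is mean(side_a) - mean(side_b) on the (log) expression scale.
    With fewer than 2 observations on a side the method falls back to the
    ordinary pooled t-test (logged warning).

    Returns a DataFrame indexed by feature with columns mean_side_a,
    mean_side_b, effect, t, df, p, q.
    """
    side_a, side_b = partition
    if set(side_a) & set(side_b):
        raise ValueError("partition sides overlap")
    idx = {o: j for j, o in enumerate(matrix.observation_ids)}
    xa = matrix.values[:, [idx[o] for o in side_a]]
    xb = matrix.values[:, [idx[o] for o in side_b]]
    na, nb = xa.shape[1], xb.shape[1]
    if na < 1 or nb < 1:
        raise ValueError("both sides must be nonempty")
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    effect = mean_a - mean_b

    df_resid = na + nb - 2
    if (na < 2 or nb < 2) or df_resid < 1:
        moderated = False
        log.warning("differential_expression: a side has <2 observations; "
                    "using the ordinary t-test")
    ss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + \
         ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    if df_resid >= 1:
        s2 = ss / df_resid
    else:
        s2 = np.zeros_like(ss)

    if moderated:
        d0, s02 = fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
        else:
            s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    else:
        s2_post = s2
        df_total = float(max(df_resid, 1))

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = np.zeros_like(effect)
    nz = se > 0
    t[nz] = effect[nz] / se[nz]
    t[(~nz) & (effect != 0)] = np.inf * np.sign(effect[(~nz) & (effect != 0)])
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p[(~nz) & (effect == 0)] = 1.0
    p = np.clip(p, 0.0, 1.0)
    out = pd.DataFrame({
        "mean_side_a": mean_a, "mean_side_b": mean_b, "effect": effect,
        "t": t, "df": df_total, "p": p, "q": fdr_adjust(p),
    }, index=pd.Index(matrix.feature_ids, name="feature"))
    return out


def derive_signature(result: pd.DataFrame, rule: SignatureRule = SignatureRule(),
                     direction: str = "up") -> list[str]:
    """Signature of up-regulated features: q, own-side mean and size caps.

    Features with q < rule.fdr_max, positive effect and side-a mean above
    rule.min_mean, ranked by q then |t|, truncated at rule.max_genes.
    """
    if direction != "up":
        raise ValueError("only up-regulated signatures are defined")
    ok = (result["q"] < rule.fdr_max) & (result["effect"] > 0) & \
         (result["mean_side_a"] > rule.min_mean)
    sub = result.loc[ok].copy()
    sub["_abs_t"] = -np.abs(sub["t"])
    sub = sub.sort_values(["q", "_abs_t"], kind="stable")
    return list(sub.index[: rule.max_genes])


# ----------------------------------------------------------------------
# gene sets
# ----------------------------------------------------------------------

def read_gmt_dict(path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> member genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {ln}: need name, description, >=1 member")
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError("empty GMT file")
    return sets


def hypergeometric_enrichment(signature: list[str], sets: dict[str, list[str]],
                              universe: list[str]) -> pd.DataFrame:
    """One-sided (upper tail) hypergeometric over-representation per set."""
    uni = set(universe)
    sig = set(signature)
    if not sig <= uni:
        raise ValueError("signature must be a subset of the universe")
    m = len(uni)
    n_sig = len(sig)
    rows = []
    for name, members in sets.items():
        in_uni = sorted(set(members) & uni)
        if not in_uni:
            log.warning("gene set %r has no overlap with the universe; skipped", name)
            continue
        k = len(sig & set(in_uni))
        p = float(stats.hypergeom.sf(k - 1, m, len(in_uni), n_sig))
        rows.append({"set": name, "n_set": len(in_uni), "n_signature": n_sig,
                     "n_overlap": k, "p": min(p, 1.0),
                     "overlap": ";".join(sorted(sig & set(in_uni)))})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = fdr_adjust(out["p"].to_numpy())
        out = out.set_index("set")
    return out


def project_gene_sets(matrix: ExpressionMatrix,
                      sets: dict[str, list[str]]) -> pd.DataFrame:
    """Single-sample gene-set projection scores (sets x observations).

    Per observation the features are ranked (average ranks on ties); the
    score is the normalized difference between the mean rank of in-set and
    out-of-set features, scaled to [-1, 1] (1 when the set occupies the top
    |S| ranks).  Invariant under monotone transforms of the observation's
    values.  Sets with fewer than 2 present features score NaN.
    """
    f = matrix.n_features
    ranks = np.apply_along_axis(stats.rankdata, 0, matrix.values)
    feat_index = {g: i for i, g in enumerate(matrix.feature_ids)}
    scores = {}
    for name, members in sets.items():
        rows = sorted({feat_index[g] for g in members if g in feat_index})
        s = len(rows)
        if s < 2 or s >= f:
            log.warning("gene set %r has %d usable features; score undefined", name, s)
            scores[name] = np.full(matrix.n_observations, np.nan)
            continue
        in_mean = ranks[rows, :].mean(axis=0)
        out_mean = (ranks.sum(axis=0) - ranks[rows, :].sum(axis=0)) / (f - s)
        scores[name] = (in_mean - out_mean) / (f / 2.0)
    return pd.DataFrame(scores, index=matrix.observation_ids).T


# ----------------------------------------------------------------------
# phenotype tests
# ----------------------------------------------------------------------

def _fisher_sim_p(table: np.ndarray, n_draws: int, seed: int) -> float:
    """Monte-Carlo Fisher p for an L x 2 table (fixed margins).

    p = share of permutation tables whose conditional probability is no
    larger than the observed one (with the observed table counted).
    """
    rng = np.random.default_rng(seed)
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    levels = np.repeat(np.arange(len(row_m)), row_m)

    def log_prob(t: np.ndarray) -> float:
        return float(gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum()
                     - gammaln(row_m.sum() + 1) - gammaln(t + 1).sum())

    obs = log_prob(table)
    hits = 1
    for _ in range(n_draws):
        perm = rng.permutation(levels)
        t = np.stack([np.bincount(perm[:col_m[0]], minlength=len(row_m)),
                      np.bincount(perm[col_m[0]:], minlength=len(row_m))], axis=1)
        if log_prob(t) <= obs + 1e-12:
            hits += 1
    return hits / (n_draws + 1)


def phenotype_tests(phenotypes: pd.DataFrame, types: dict[str, str],
                    partition: tuple[list[str], list[str]],
                    continuous_test: str = "t", n_draws: int = 100_000,
                    seed: int = 0) -> pd.DataFrame:
    """Two-sided association tests of each variable with the partition.

    ``phenotypes`` is observations x variables; ``types`` maps each column
    to "continuous" or "categorical".  Continuous variables use Student's t
    or the exact Wilcoxon rank-sum; categorical use Fisher's exact test
    (Monte-Carlo for more than two levels).  Constant variables get p = 1
    with a flag.  q is BH across the tested variables.
    """
    side_a, side_b = partition
    rows = []
    for var in phenotypes.columns:
        kind = types.get(var)
        if kind not in ("continuous", "categorical"):
            raise ValueError(f"variable {var!r} has no declared type")
        a = phenotypes.loc[[o for o in side_a if o in phenotypes.index], var].dropna()
        b = phenotypes.loc[[o for o in side_b if o in phenotypes.index], var].dropna()
        rec = {"variable": var, "type": kind, "n_side_a": len(a), "n_side_b": len(b),
               "statistic": np.nan, "p": np.nan, "flag": ""}
        pooled = pd.concat([a, b])
        if len(a) == 0 or len(b) == 0:
            rec["flag"] = "empty-side"
            rec["p"] = 1.0
        elif pooled.nunique() < 2:
            rec["flag"] = "constant"
            rec["p"] = 1.0
        elif kind == "continuous":
            av = a.astype(float).to_numpy()
            bv = b.astype(float).to_numpy()
            if continuous_test == "t":
                res = stats.ttest_ind(av, bv, equal_var=True)
            elif continuous_test == "wilcoxon":
                res = stats.mannwhitneyu(av, bv, alternative="two-sided",
                                         method="exact" if len(av) + len(bv) <= 40
                                         else "asymptotic")
            else:
                raise ValueError(f"unknown continuous_test {continuous_test!r}")
            rec["statistic"] = float(res.statistic)
            rec["p"] = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        else:
            levels = sorted(pooled.astype(str).unique())
            table = np.stack([
                np.array([int((a.astype(str) == lv).sum()) for lv in levels]),
                np.array([int((b.astype(str) == lv).sum()) for lv in levels]),
            ], axis=1)
            if len(levels) == 2:
                stat, p = stats.fisher_exact(table.T, alternative="two-sided")
                rec["statistic"] = float(stat)
                rec["p"] = float(p)
            else:
                rec["p"] = _fisher_sim_p(table, n_draws, seed)
                rec["flag"] = "simulated"
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("variable")
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


# ----------------------------------------------------------------------
# whole-taxonomy annotation
# ----------------------------------------------------------------------

def _node_observations(taxonomy, matrix: ExpressionMatrix, node) -> list[str]:
    if taxonomy.mode == "observation":
        return list(node.member_items)
    keep = set(node.member_items)
    return [o for o in matrix.observation_ids if matrix.group_labels[o] in keep]


def annotate_taxonomy(taxonomy, matrix: ExpressionMatrix,
                      gene_sets: dict[str, list[str]] | None = None,
                      phenotypes: pd.DataFrame | None = None,
                      phenotype_types: dict[str, str] | None = None,
                      signature_rule: SignatureRule = SignatureRule(),
                      continuous_test: str = "t",
                      seed: int = 0) -> dict[str, dict[str, pd.DataFrame]]:
    """Annotate every internal partition of a fitted taxonomy.

    For each internal node the two children define side A and side B; the
    returned mapping node_id -> tables holds "differential" (one frame per
    side comparison, side A = first child), "signature", and, when inputs
    are provided, "enrichment", "projection_differential" and "phenotypes".
    """
    projections = None
    if gene_sets:
        projections = project_gene_sets(matrix, gene_sets)
    out: dict[str, dict] = {}
    for node in taxonomy.internal_nodes():
        side_a = _node_observations(taxonomy, matrix, node.children[0])
        side_b = _node_observations(taxonomy, matrix, node.children[1])
        tables: dict[str, object] = {}
        de = differential_expression(matrix, (side_a, side_b))
        tables["differential"] = de
        signature = derive_signature(de, signature_rule)
        tables["signature"] = signature
        if gene_sets:
            if signature:
                tables["enrichment"] = hypergeometric_enrichment(
                    signature, gene_sets, matrix.feature_ids)
            else:
                tables["enrichment"] = pd.DataFrame()
            proj = projections.dropna(how="any")
            if len(proj):
                proj_matrix = ExpressionMatrix(
                    proj.to_numpy(), list(proj.index), list(proj.columns))
                tables["projection_differential"] = differential_expression(
                    proj_matrix, (side_a, side_b))
        if phenotypes is not None:
            if phenotype_types is None:
                raise ValueError("phenotype_types required with phenotypes")
            tables["phenotypes"] = phenotype_tests(
                phenotypes, phenotype_types, (side_a, side_b),
                continuous_test=continuous_test, seed=seed)
        out[node.node_id] = tables
    return out
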