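import itertools
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import rankdata, t as t_dist

from k2tax import (ExpressionMatrix, SignatureRule, derive_signature,
                   differential_expression, fdr_adjust,
                   hypergeometric_enrichment, phenotype_tests,
                   project_gene_sets)
from k2tax.annotation import annotate_taxonomy


def _matrix(values):
    f, n = np.asarray(values).shape
    return ExpressionMatrix(values, [f"g{i}" for i in range(f)],
                            [f"o{j}" for j in range(n)])


def oracle_moderated_t(x, na):
    """Independently coded empirical-Bayes shrinkage (shared formulas,
    separate implementation path) returning (t, p)."""
    xa, xb = x[:, :na], x[:, na:]
    nb = x.shape[1] - na
    d = na + nb - 2
    eff = xa.mean(1) - xb.mean(1)
    s2 = (xa.var(1, ddof=1) * (na - 1) + xb.var(1, ddof=1) * (nb - 1)) / d
    e = np.log(s2) - digamma(d / 2) + math.log(d / 2)
    ev = np.var(e, ddof=1) - polygamma(1, d / 2)
    if ev > 0:
        lo, hi = 1e-8, 1e8     # bisection inverse of trigamma
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if polygamma(1, mid) > ev:
                lo = mid
            else:
                hi = mid
        d0 = 2 * lo
        s02 = math.exp(np.mean(e) + digamma(d0 / 2) - math.log(d0 / 2))
        s2p = (d0 * s02 + d * s2) / (d0 + d)
        dft = d + d0
    else:
        s2p = np.full_like(s2, s2.mean())
        dft = np.inf
    tt = eff / np.sqrt(s2p * (1 / na + 1 / nb))
    if np.isinf(dft):
        from scipy.stats import norm
        pp = 2 * norm.sf(np.abs(tt))
    else:
        pp = 2 * t_dist.sf(np.abs(tt), dft)
    return tt, pp


class TestDifferentialExpression:
    def test_shifted_feature_ranks_first_and_matches_oracle(self):
        rng = np.random.default_rng(0)
        sd = np.exp(rng.normal(0, 0.5, 150))
        x = rng.normal(0, 1, (150, 20)) * sd[:, None]
        x[0, :10] += 5 * sd[0]
        m = _matrix(x)
        obs = m.observation_ids
        res = differential_expression(m, (obs[:10], obs[10:]))
        assert res["p"].idxmin() == "g0"
        tt, pp = oracle_moderated_t(x, 10)
        assert np.max(np.abs(res["t"].to_numpy() - tt)) < 1e-8
        assert np.max(np.abs(res["p"].to_numpy() - pp)) < 1e-8

    def test_matches_bioconductor_limma(self, tmp_path):
        rng = np.random.default_rng(7)
        sd = np.exp(rng.normal(0, 0.8, 120))
        x = rng.normal(0, 1, (120, 14)) * sd[:, None]
        x[:6, :7] += 2.5
        mat = tmp_path / "mat.tsv"
        pd.DataFrame(x, index=[f"g{i}" for i in range(120)]).to_csv(mat, sep="\t")
        script = tmp_path / "limma.R"
        out = tmp_path / "out.tsv"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'x <- as.matrix(read.delim("{mat}", row.names=1))\n'
            'design <- cbind(Intercept=1, side=c(rep(1,7), rep(0,7)))\n'
            'fit <- eBayes(lmFit(x, design))\n'
            'out <- data.frame(t=fit$t[,"side"], p=fit$p.value[,"side"])\n'
            f'write.table(out, "{out}", sep="\\t", quote=FALSE)\n')
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(out, sep="\t")
        m = _matrix(x)
        obs = m.observation_ids
        res = differential_expression(m, (obs[:7], obs[7:]))
        assert np.max(np.abs(res["t"].to_numpy() - ref["t"].to_numpy())) < 1e-8
        assert np.max(np.abs(res["p"].to_numpy() - ref["p"].to_numpy())) < 1e-8

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (2000, 20))
        m = _matrix(x)
        obs = m.observation_ids
        res = differential_expression(m, (obs[:10], obs[10:]))
        frac = float((res["p"] < 0.05).mean())
        assert abs(frac - 0.05) < 0.02

    def test_identical_feature_has_zero_effect_unit_p(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (30, 12))
        x[4, :6] = x[4, 6:]     # identical values on both sides
        m = _matrix(x)
        obs = m.observation_ids
        res = differential_expression(m, (obs[:6], obs[6:]))
        assert res.loc["g4", "effect"] == pytest.approx(0.0)
        assert res.loc["g4", "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["g4", "p"] == pytest.approx(1.0)

    def test_side_swap_negates_effects_keeps_p(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (40, 16))
        x[:5, :8] += 1.0
        m = _matrix(x)
        obs = m.observation_ids
        a = differential_expression(m, (obs[:8], obs[8:]))
        b = differential_expression(m, (obs[8:], obs[:8]))
        assert np.allclose(a["effect"], -b["effect"])
        assert np.allclose(a["t"], -b["t"])
        assert np.allclose(a["p"], b["p"])
        assert np.allclose(a["q"], b["q"])

    def test_small_side_falls_back_to_ordinary_t(self, caplog):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (10, 5))
        m = _matrix(x)
        obs = m.observation_ids
        with caplog.at_level("WARNING", logger="k2tax"):
            res = differential_expression(m, (obs[:1], obs[1:]))
        assert "ordinary t" in caplog.text
        assert np.isfinite(res["p"]).all()


class TestSignature:
    @staticmethod
    def _result(n_pass, n_total=120, seed=0):
        rng = np.random.default_rng(seed)
        q = np.concatenate([10.0 ** -rng.uniform(11, 20, n_pass),
                            10.0 ** -rng.uniform(0, 9, n_total - n_pass)])
        return pd.DataFrame({
            "mean_side_a": np.full(n_total, 2.0), "mean_side_b": 0.0,
            "effect": 2.0, "t": rng.normal(8, 1, n_total),
            "p": q, "q": q,
        }, index=[f"g{i}" for i in range(n_total)])

    def test_capped_at_max_genes(self):
        res = self._result(60)
        sig = derive_signature(res, SignatureRule(1e-10, 0.5, 50))
        assert len(sig) == 50
        worst_in = res.loc[sig, "q"].max()
        best_out = res.loc[res.index.difference(sig), "q"]
        best_out = best_out[best_out < 1e-10]
        assert (best_out >= worst_in).all() or best_out.empty

    def test_no_feature_passes_gives_empty(self):
        res = self._result(0)
        assert derive_signature(res, SignatureRule(1e-10, 0.5, 50)) == []

    def test_exactly_passing_set_and_stable_order(self):
        res = self._result(50)
        sig1 = derive_signature(res, SignatureRule(1e-10, 0.5, 50))
        sig2 = derive_signature(res.copy(), SignatureRule(1e-10, 0.5, 50))
        assert len(sig1) == 50
        assert sig1 == sig2

    def test_low_expression_and_downregulated_excluded(self):
        res = self._result(10)
        res.loc["g0", "mean_side_a"] = 0.2     # below the expression floor
        res.loc["g1", "effect"] = -1.0         # down-regulated
        sig = derive_signature(res, SignatureRule(1e-10, 0.5, 50))
        assert "g0" not in sig and "g1" not in sig


class TestEnrichment:
    def test_closed_form_example(self):
        universe = [f"u{i}" for i in range(10)]
        sets = {"S": universe[:5]}
        sig = universe[:4]
        out = hypergeometric_enrichment(sig, sets, universe)
        assert out.loc["S", "p"] == pytest.approx(
            math.comb(5, 4) * math.comb(5, 0) / math.comb(10, 4))

    def test_signature_equal_to_universe(self):
        universe = [f"u{i}" for i in range(10)]
        sets = {"S": universe[:5]}
        out = hypergeometric_enrichment(universe, sets, universe)
        assert out.loc["S", "n_overlap"] == 5
        assert out.loc["S", "p"] == pytest.approx(1.0)

    def test_overlap_at_null_expectation_not_significant(self):
        # universe 20, set 10, signature 8 -> expected overlap 4; brute-force
        # upper tail P(X >= 4)
        universe = [f"u{i}" for i in range(20)]
        sets = {"S": universe[:10]}
        sig = universe[:4] + universe[10:14]   # overlap exactly 4
        out = hypergeometric_enrichment(sig, sets, universe)
        tail = sum(math.comb(10, k) * math.comb(10, 8 - k) for k in range(4, 9)) \
            / math.comb(20, 8)
        assert out.loc["S", "p"] == pytest.approx(tail)
        assert out.loc["S", "p"] >= 0.5

    def test_zero_overlap_set_skipped(self, caplog):
        universe = [f"u{i}" for i in range(6)]
        sets = {"S": ["nope1", "nope2"], "T": universe[:3]}
        with caplog.at_level("WARNING", logger="k2tax"):
            out = hypergeometric_enrichment(universe[:2], sets, universe)
        assert list(out.index) == ["T"]
        assert "no overlap" in caplog.text


class TestProjection:
    def test_top_ranked_set_scores_one(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.normal(size=(100, 3)), axis=0)   # ascending per column
        m = _matrix(x)
        sets = {"top": [f"g{i}" for i in range(90, 100)]}
        scores = project_gene_sets(m, sets)
        assert np.allclose(scores.loc["top"], 1.0)

    def test_interleaved_set_scores_near_zero(self):
        # members occupying evenly spaced ranks: mean in-set and out-of-set
        # ranks coincide up to O(1/F)
        rng = np.random.default_rng(1)
        x = np.sort(rng.normal(size=(500, 4)), axis=0)
        m = _matrix(x)
        members = [f"g{i}" for i in range(0, 500, 10)]   # every 10th rank, S=50
        scores = project_gene_sets(m, {"S": members})
        assert np.all(np.abs(scores.loc["S"]) < 0.05)
        # permutation null: random sets of the same size stay near zero on
        # the scale of their standard error 0.577/sqrt(S)
        null = np.concatenate([
            project_gene_sets(m, {"S": [f"g{i}" for i in
                rng.choice(500, 50, replace=False)]}).loc["S"].to_numpy()
            for _ in range(25)])
        assert abs(null.mean()) < 3 * 0.577 / math.sqrt(50) / math.sqrt(len(null))

    def test_monotone_transform_invariance_and_bounds(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(80, 5))
        m = _matrix(x)
        sets = {"S": [f"g{i}" for i in range(0, 40, 3)]}
        s1 = project_gene_sets(m, sets)
        x2 = x.copy()
        x2[:, 2] = np.exp(x2[:, 2])          # monotone transform of one column
        s2 = project_gene_sets(_matrix(x2), sets)
        assert np.allclose(s1.to_numpy(), s2.to_numpy())
        assert (s1.abs() <= 1.0 + 1e-12).all().all()

    def test_too_small_set_flagged_missing(self, caplog):
        m = _matrix(np.random.default_rng(3).normal(size=(20, 3)))
        with caplog.at_level("WARNING", logger="k2tax"):
            scores = project_gene_sets(m, {"tiny": ["g1"]})
        assert scores.loc["tiny"].isna().all()


def fisher_enumeration_p(table):
    """Exact two-sided Fisher p for a 2x2 table by enumerating the margin-
    preserving tables and summing those no more probable than observed."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def log_prob(aa):
        return (gammaln(r1 + 1) + gammaln(r2 + 1) + gammaln(c1 + 1)
                + gammaln(n - c1 + 1) - gammaln(n + 1)
                - gammaln(aa + 1) - gammaln(r1 - aa + 1)
                - gammaln(c1 - aa + 1) - gammaln(r2 - c1 + aa + 1))

    obs = log_prob(a)
    p = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        lp = log_prob(aa)
        if lp <= obs + 1e-10:
            p += math.exp(lp)
    return min(p, 1.0)


class TestPhenotypes:
    def _run(self, values_a, values_b, kind, **kw):
        obs = [f"a{i}" for i in range(len(values_a))] + \
            [f"b{i}" for i in range(len(values_b))]
        phen = pd.DataFrame({"v": list(values_a) + list(values_b)}, index=obs)
        return phenotype_tests(phen, {"v": kind},
                               ([o for o in obs if o.startswith("a")],
                                [o for o in obs if o.startswith("b")]), **kw)

    def test_fisher_matches_enumeration_oracle(self):
        out = self._run(["x"] * 8 + ["y"] * 2, ["x"] * 1 + ["y"] * 9, "categorical")
        expected = fisher_enumeration_p([[8, 2], [1, 9]])
        assert out.loc["v", "p"] == pytest.approx(expected, rel=1e-10)

    def test_identical_continuous_sides(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        out = self._run(vals, vals, "continuous")
        assert out.loc["v", "p"] == pytest.approx(1.0)

    def test_wilcoxon_fully_separated_exact_tail(self):
        out = self._run(np.arange(10), np.arange(100, 110), "continuous",
                        continuous_test="wilcoxon")
        assert out.loc["v", "p"] == pytest.approx(2 / math.comb(20, 10))

    def test_constant_variable_flagged(self):
        out = self._run([1.0] * 5, [1.0] * 5, "continuous")
        assert out.loc["v", "p"] == 1.0
        assert out.loc["v", "flag"] == "constant"

    def test_multilevel_simulation_close_to_enumeration(self):
        # 3x2 table: exact p by full enumeration of margin-preserving tables
        table = np.array([[5, 1], [2, 6], [1, 5]])
        row_m, col_m = table.sum(1), table.sum(0)

        def log_prob(t):
            return float(gammaln(row_m + 1).sum() + gammaln(col_m + 1).sum()
                         - gammaln(row_m.sum() + 1) - gammaln(t + 1).sum())

        obs = log_prob(table)
        p_exact = 0.0
        for a in range(min(row_m[0], col_m[0]) + 1):
            for b in range(min(row_m[1], col_m[0] - a) + 1):
                c = col_m[0] - a - b
                if 0 <= c <= row_m[2]:
                    t = np.array([[a, row_m[0] - a], [b, row_m[1] - b],
                                  [c, row_m[2] - c]])
                    lp = log_prob(t)
                    if lp <= obs + 1e-10:
                        p_exact += math.exp(lp)
        vals_a = ["x"] * 5 + ["y"] * 2 + ["z"] * 1
        vals_b = ["x"] * 1 + ["y"] * 6 + ["z"] * 5
        out = self._run(vals_a, vals_b, "categorical", n_draws=20000, seed=1)
        assert out.loc["v", "flag"] == "simulated"
        assert out.loc["v", "p"] == pytest.approx(p_exact, abs=0.02)


class TestFDR:
    def test_hand_computed_step_up(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert fdr_adjust([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_hand_coded_step_up_on_random_vectors(self):
        def bh_oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p, kind="stable")
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.allclose(fdr_adjust(p), bh_oracle(p), atol=1e-12)

    def test_nan_p_dropped(self):
        q = fdr_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[[0, 2]]).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestAnnotateTaxonomy:
    def test_full_pipeline_tables(self, sim_taxonomy):
        tax, matrix = sim_taxonomy["taxonomy"], sim_taxonomy["matrix"]
        rng = np.random.default_rng(0)
        sets = {f"set{k}": [f"gene{j:05d}" for j in
                            rng.choice(500, 25, replace=False)] for k in range(4)}
        phen = pd.DataFrame({
            "score": rng.normal(size=matrix.n_observations),
            "grade": rng.choice(["lo", "hi"], matrix.n_observations),
        }, index=matrix.observation_ids)
        res = annotate_taxonomy(tax, matrix, gene_sets=sets, phenotypes=phen,
                                phenotype_types={"score": "continuous",
                                                 "grade": "categorical"})
        assert set(res) == {n.node_id for n in tax.internal_nodes()}
        for tables in res.values():
            de = tables["differential"]
            assert len(de) == matrix.n_features
            assert ((de["q"] >= 0) & (de["q"] <= 1)).all()
            assert set(tables["phenotypes"].index) == {"score", "grade"}
            assert "projection_differential" in tables

    def test_null_pipeline_controls_fdr(self):
        # global null: no feature differs between sides; across 20 seeded
        # replicates the empirical FDR at q <= 0.1 stays small
        false_hits, tests = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(300, 16))
            m = _matrix(x)
            obs = m.observation_ids
            res = differential_expression(m, (obs[:8], obs[8:]))
            false_hits += int((res["q"] <= 0.1).sum())
            tests += 1
        assert false_hits / (tests * 300) <= 0.15
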