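"""Mixed-model association machinery and downstream statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from mirvar.assoc import (
    LMMFit,
    bh_fdr,
    build_design,
    candidate_targets,
    centered_kinship,
    ddct_quantify,
    eigendecompose_kinship,
    filter_expressed_probes,
    fit_lmm,
    hypergeom_enrichment,
    lrt,
    welch_t,
)


class TestFilterExpressedProbes:
    def make_presence(self, fracs, n=100):
        return pd.DataFrame(
            {
                f"s{j}": [j < f * n for f in fracs]
                for j in range(n)
            },
            index=[f"p{i}" for i in range(len(fracs))],
        )

    def test_boundaries(self):
        presence = self.make_presence([1.0, 0.49, 0.5, 0.51])
        kept = filter_expressed_probes(presence)
        assert kept == ["p0", "p2", "p3"]  # exactly 50% retained, 49% dropped

    def test_controls_always_dropped(self):
        presence = self.make_presence([1.0, 1.0])
        assert filter_expressed_probes(presence, control_probes=["p1"]) == ["p0"]


class TestCenteredKinship:
    def test_identical_individuals(self):
        G = np.array([[0, 1, 2], [0, 1, 2]], dtype=float)
        K = centered_kinship(G)
        assert K[0, 0] == pytest.approx(K[0, 1])
        assert K[0, 0] == pytest.approx(K[1, 1])

    def test_single_snp_hand_product(self):
        K = centered_kinship(np.array([[0.0], [2.0]]))
        assert K == pytest.approx(np.array([[1, -1], [-1, 1]]))

    def test_mean_imputation(self):
        K = centered_kinship(np.array([[0.0], [np.nan], [2.0]]))
        expected = np.outer([-1, 0, 1], [-1, 0, 1])
        assert K == pytest.approx(expected)

    def test_all_missing_column_dropped(self):
        G = np.array([[0, np.nan], [2, np.nan], [1, np.nan]])
        K = centered_kinship(G)
        assert K.shape == (3, 3)


class TestFitLmm:
    def test_identity_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(0)
        n = 60
        W = np.column_stack([np.ones(n), rng.standard_normal(n)])
        x = rng.standard_normal(n)
        y = W @ [1.0, 0.5] + 0.4 * x + rng.standard_normal(n)
        fit = fit_lmm(y, W, x, K=np.eye(n))
        beta = np.linalg.lstsq(np.column_stack([W, x]), y, rcond=None)[0]
        assert fit.delta == pytest.approx(beta[-1], abs=1e-6)

    def test_loglik_matches_direct_mvn_density(self):
        """On an n=6 fixture the reported logL equals the multivariate
        normal density with covariance tau^-1 (lambda K + I)."""
        rng = np.random.default_rng(4)
        n = 6
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        W = np.ones((n, 1))
        x = rng.standard_normal(n)
        y = rng.standard_normal(n) + x
        fit = fit_lmm(y, W, x, K=K)
        cov = fit.sigma2 * (fit.lam * K + np.eye(n))
        mean = W @ fit.alpha + x * fit.delta
        direct = multivariate_normal(mean=mean, cov=cov).logpdf(y)
        assert fit.log_likelihood == pytest.approx(direct, abs=1e-8)

    def test_optimum_not_improved_by_nearby_lambda(self):
        rng = np.random.default_rng(5)
        n = 40
        G = rng.integers(0, 3, size=(n, 60)).astype(float)
        K = centered_kinship(G)
        W = np.ones((n, 1))
        y = rng.standard_normal(n)
        fit = fit_lmm(y, W, None, K=K)
        for lam in (fit.lam * 0.5, fit.lam * 2):
            # refit residual variance at the trial lambda before comparing
            alt = _direct_ml_loglik(y, W, K, lam)
            assert fit.log_likelihood >= alt - 1e-6

    def test_constant_snp_flagged(self):
        rng = np.random.default_rng(6)
        n = 20
        fit = fit_lmm(
            rng.standard_normal(n), np.ones((n, 1)), np.ones(n), K=np.eye(n)
        )
        assert math.isnan(fit.delta) and math.isnan(fit.se_delta)

    def test_non_psd_kinship_rejected(self):
        n = 5
        K = -np.eye(n)
        with pytest.raises(ValueError, match="PSD"):
            eigendecompose_kinship(K)

    def test_delta_recovery_small(self):
        rng = np.random.default_rng(7)
        n = 200
        G = rng.binomial(2, 0.4, size=(n, 80)).astype(float)
        K = centered_kinship(G)
        eig = eigendecompose_kinship(K)
        root = eig.vectors * np.sqrt(eig.values)
        W = np.ones((n, 1))
        x = rng.binomial(2, 0.3, size=n).astype(float)
        y = 0.45 * x + np.sqrt(0.3) * (root @ rng.standard_normal(n)) + np.sqrt(
            0.7
        ) * rng.standard_normal(n)
        fit = fit_lmm(y, W, x, eigen=eig)
        assert abs(fit.delta - 0.45) < 3 * fit.se_delta


def _direct_ml_loglik(y, W, K, lam):
    """Profile out beta and sigma2 at a fixed lambda, directly."""
    n = len(y)
    V = lam * K + np.eye(n)
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(W.T @ Vi @ W, W.T @ Vi @ y)
    r = y - W @ beta
    sigma2 = float(r @ Vi @ r) / n
    sign, logdet = np.linalg.slogdet(V)
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


class TestLrt:
    def make_fit(self, ll, n=10):
        return LMMFit(1.0, 1.0, np.zeros(1), 0.1, 0.1, ll, n)

    def test_equal_likelihoods(self):
        assert lrt(self.make_fit(-5.0), self.make_fit(-5.0)) == 1.0

    def test_chisq_quantile(self):
        p = lrt(self.make_fit(-5.0 + 3.841 / 2), self.make_fit(-5.0))
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_negative_statistic_floored(self):
        assert lrt(self.make_fit(-5.1), self.make_fit(-5.0)) == 1.0

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            lrt(self.make_fit(-5.0, n=10), self.make_fit(-5.0, n=11))


def bh_oracle(ps):
    """Step-up computation done by hand."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, ps[i] * m / rank)
        q[i] = prev
    return q


class TestBhFdr:
    def test_single(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_matches_hand_oracle_randomised(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            ps = rng.uniform(size=rng.integers(1, 40)).tolist()
            assert bh_fdr(ps) == pytest.approx(bh_oracle(ps))

    def test_bounded_and_idempotent(self):
        rng = np.random.default_rng(11)
        ps = rng.uniform(size=25)
        qs = bh_fdr(ps)
        assert np.all(qs >= ps) and np.all(qs <= 1.0)
        assert bh_fdr(qs) == pytest.approx(bh_oracle(qs.tolist()))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestHypergeomEnrichment:
    def test_zero_overlap_p_is_one(self):
        df = hypergeom_enrichment(
            ["a", "b"], {"path": ["c", "d"]}, ["a", "b", "c", "d", "e"]
        )
        assert df.iloc[0]["p"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        universe = [f"g{i}" for i in range(20)]
        pathway = universe[:5]
        hits = universe[:3] + universe[10:12]  # overlap 3
        df = hypergeom_enrichment(hits, {"pw": pathway}, universe)
        # enumerate all C(20,5) draws of the pathway, count overlap >= 3
        from itertools import combinations

        hit_set = set(hits)
        total = ok = 0
        for combo in combinations(universe, 5):
            total += 1
            if len(hit_set & set(combo)) >= 3:
                ok += 1
        assert df.iloc[0]["p"] == pytest.approx(ok / total)

    def test_perfect_overlap_most_extreme(self):
        universe = [f"g{i}" for i in range(10)]
        hits = universe[:5]
        df = hypergeom_enrichment(
            hits, {"perfect": hits, "partial": universe[3:8]}, universe
        )
        p = dict(zip(df["pathway"], df["p"]))
        assert p["perfect"] < p["partial"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["a"], {"p": ["a"]}, [])


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.288, abs=1e-3)

    def test_large_separation(self):
        _, _, p = welch_t([0.0, 0.1, 0.05, -0.02], [10.0, 10.1, 9.9, 10.05])
        assert p < 1e-4

    def test_degenerate_zero_variance(self):
        t, _, p = welch_t([1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)


class TestDdct:
    def make_ct(self, target_cts, control_ct=20.0):
        rows = []
        for sample, ct in target_cts.items():
            for rep in range(3):
                rows.append({"sample": sample, "gene": "tgt", "ct": ct})
                rows.append({"sample": sample, "gene": "ctrl", "ct": control_ct})
        return pd.DataFrame(rows)

    def test_calibrator_at_mean_has_rq_one(self):
        ct = self.make_ct({"g1": 25.0, "g2": 25.0, "a1": 24.0})
        groups = {"g1": "GG", "g2": "GG", "a1": "AA"}
        records, _ = ddct_quantify(ct, "tgt", ["ctrl"], groups, "GG")
        rq = dict(zip(records["sample"], records["rq"]))
        assert rq["g1"] == pytest.approx(1.0)

    def test_ddct_minus_one_doubles_rq(self):
        ct = self.make_ct({"g1": 25.0, "a1": 24.0})
        groups = {"g1": "GG", "a1": "AA"}
        records, _ = ddct_quantify(ct, "tgt", ["ctrl"], groups, "GG")
        rec = records.set_index("sample")
        assert rec.loc["a1", "ddct"] == pytest.approx(-1.0)
        assert rec.loc["a1", "rq"] == pytest.approx(2.0)
        assert rec.loc["a1", "log2_rq"] == pytest.approx(1.0)

    def test_missing_control_rejected(self):
        ct = self.make_ct({"g1": 25.0})
        with pytest.raises(ValueError, match="control"):
            ddct_quantify(ct, "tgt", [], {"g1": "GG"}, "GG")

    def test_simulated_fold_change_recovered(self, small_cohort):
        records, comparison = ddct_quantify(
            small_cohort.ct_table,
            "mir_target",
            ["ctrl_let7a", "ctrl_mir26a"],
            small_cohort.ct_groups,
            "GG",
        )
        fold = comparison["groups"]["AA"]["mean_rq"]
        assert fold == pytest.approx(small_cohort.truth["fold_effect"], rel=0.15)
        assert "p" in comparison["groups"]["AA"]


class TestCandidateTargets:
    pairs = pd.DataFrame(
        [
            {"mirna_arm_id": "armA", "gene_id": "g1", "transcript_id": "t1",
             "n_7mer_m8": 1, "n_8mer": 0},
            {"mirna_arm_id": "armA", "gene_id": "g2", "transcript_id": "t2",
             "n_7mer_m8": 0, "n_8mer": 1},
        ]
    )
    probe_gene = pd.DataFrame(
        [{"probe": "p1", "gene": "g1"}, {"probe": "p2", "gene": "g2"},
         {"probe": "p3", "gene": "g3"}]
    )

    def test_not_validated_excluded(self):
        validated = pd.DataFrame([{"mirna": "armA", "gene": "g1"}])
        out = candidate_targets(
            {"rs1": "armA"}, self.pairs, validated, ["p1", "p2", "p3"],
            self.probe_gene,
        )
        assert set(out["gene"]) == {"g1"}  # g2 has a site but is not validated

    def test_all_conditions_met_included(self):
        validated = pd.DataFrame(
            [{"mirna": "armA", "gene": "g1"}, {"mirna": "armA", "gene": "g2"}]
        )
        out = candidate_targets(
            {"rs1": "armA"}, self.pairs, validated, ["p1", "p2"], self.probe_gene
        )
        assert set(out["probe"]) == {"p1", "p2"}

    def test_unexpressed_probe_excluded(self):
        validated = pd.DataFrame([{"mirna": "armA", "gene": "g1"}])
        out = candidate_targets(
            {"rs1": "armA"}, self.pairs, validated, ["p2"], self.probe_gene
        )
        assert out.empty

    def test_condition_free_mode(self):
        validated = pd.DataFrame(columns=["mirna", "gene"])
        out = candidate_targets(
            {"rs1": "armA"}, self.pairs, validated, ["p1", "p2", "p3"],
            self.probe_gene, require_site=False, require_validated=False,
        )
        assert set(out["probe"]) == {"p1", "p2", "p3"}


class TestBuildDesign:
    def test_reference_coding_first_level_baseline(self):
        cov = pd.DataFrame({"batch": ["b1", "b2", "b1", "b3"]})
        W = build_design(cov, factors=["batch"])
        assert W.shape == (4, 3)  # intercept + 2 indicator columns
        assert W[0].tolist() == [1.0, 0.0, 0.0]

    def test_redundant_column_dropped(self):
        cov = pd.DataFrame(
            {"a": ["x", "y", "x", "y"], "b": ["u", "v", "u", "v"]}
        )
        W = build_design(cov, factors=["a", "b"])  # b duplicates a
        assert W.shape[1] == 2
        assert np.linalg.matrix_rank(W) == W.shape[1]
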