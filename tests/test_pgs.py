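"""Threshold grids, clumping, scoring and threshold selection."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as smapi

from pathpgs import (
    ScoreMatrix,
    SumStats,
    ThresholdGrid,
    clump,
    make_grid,
    score,
    score_matrix,
    select_threshold,
)

from conftest import random_genotypes, sumstats_for


class TestMakeGrid:
    def test_default_range_endpoints(self):
        g = make_grid(5e-8, 1, 0.001)
        assert g.thresholds[0] == 5e-8
        assert g.thresholds[-1] == 1.0

    def test_default_grid_has_1001_thresholds(self):
        # {floor} U {k*0.001 : k=1..1000} U {1.0}, deduplicated
        assert len(make_grid(5e-8, 1, 0.001)) == 1001

    def test_degenerate_step(self):
        assert list(make_grid(0.5, 1, 1).thresholds) == [0.5, 1.0]

    def test_floor_above_upper_raises(self):
        with pytest.raises(ValueError):
            make_grid(0.5, 0.1, 0.01)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            ThresholdGrid(np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            ThresholdGrid(np.array([0.0, 0.5]))


class TestSumStatsValidation:
    def test_rejects_bad_p(self):
        t = pd.DataFrame(
            {"id": ["a"], "chrom": "1", "bp": [1], "a1": ["A"], "a2": ["G"],
             "beta": [0.1], "se": [0.1], "p": [0.0]}
        )
        with pytest.raises(ValueError, match="p-values"):
            SumStats(t)

    def test_rejects_duplicate_ids(self):
        t = pd.DataFrame(
            {"id": ["a", "a"], "chrom": "1", "bp": [1, 2], "a1": ["A", "A"],
             "a2": ["G", "G"], "beta": [0.1, 0.2], "se": [0.1, 0.1],
             "p": [0.5, 0.5]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            SumStats(t)


class TestClump:
    def test_single_snp_retained(self):
        rng = np.random.default_rng(0)
        g = random_genotypes(rng, 50, 1)
        ss = sumstats_for(g, rng)
        assert clump(ss, g, ["rs0"]) == ["rs0"]

    def test_perfect_ld_keeps_most_significant(self):
        rng = np.random.default_rng(1)
        g = random_genotypes(rng, 80, 3, bp_step=100)
        # make all three columns identical (r^2 = 1)
        g.dosages[:, 1] = g.dosages[:, 0]
        g.dosages[:, 2] = g.dosages[:, 0]
        ss = sumstats_for(g, rng, betas=[0.1, 0.1, 0.1])
        ss.table.loc[:, "p"] = [1e-6, 1e-8, 1e-4]
        assert clump(ss, g, ["rs0", "rs1", "rs2"]) == ["rs1"]

    def test_independent_snps_both_kept(self):
        rng = np.random.default_rng(2)
        n = 2000
        g = random_genotypes(rng, n, 2, bp_step=100)
        # orthogonalize column 1 against column 0 to force r ~= 0
        a, b = g.dosages[:, 0], g.dosages[:, 1]
        resid = b - np.polyval(np.polyfit(a, b, 1), a)
        g.dosages[:, 1] = np.round(np.clip(resid - resid.min(), 0, 2))
        ss = sumstats_for(g, rng)
        r = np.corrcoef(g.dosages[:, 0], g.dosages[:, 1])[0, 1]
        if r**2 <= 0.1:  # guard: construction succeeded
            assert set(clump(ss, g, ["rs0", "rs1"])) == {"rs0", "rs1"}

    def test_contains_globally_most_significant(self):
        rng = np.random.default_rng(3)
        g = random_genotypes(rng, 100, 20, bp_step=1000)
        ss = sumstats_for(g, rng)
        kept = clump(ss, g, list(g.snps["id"]))
        best = ss.table.sort_values("p")["id"].iloc[0]
        assert best in kept

    def test_distant_snps_not_clumped(self):
        rng = np.random.default_rng(4)
        g = random_genotypes(rng, 60, 2, bp_step=500_000)
        g.dosages[:, 1] = g.dosages[:, 0]  # identical but 500 kb apart
        ss = sumstats_for(g, rng)
        assert len(clump(ss, g, ["rs0", "rs1"], window_kb=250)) == 2


class TestScore:
    def test_zero_betas_zero_scores(self):
        rng = np.random.default_rng(0)
        g = random_genotypes(rng, 10, 5)
        ss = sumstats_for(g, rng, betas=np.zeros(5))
        assert np.allclose(score(g, ss, list(g.snps["id"])), 0)

    def test_single_snp_dosage_weighting(self):
        snps = pd.DataFrame(
            {"id": ["rs0"], "chrom": "1", "bp": [100], "a1": ["A"], "a2": ["G"]}
        )
        g_obj = type(random_genotypes(np.random.default_rng(0), 1, 1))(
            individuals=["a", "b", "c"], snps=snps,
            dosages=np.array([[0.0], [1.0], [2.0]]),
        )
        ss = SumStats(pd.DataFrame(
            {"id": ["rs0"], "chrom": "1", "bp": [100], "a1": ["A"], "a2": ["G"],
             "beta": [0.5], "se": [0.1], "p": [0.5]}
        ))
        assert np.allclose(score(g_obj, ss, ["rs0"]), [0.0, 0.5, 1.0])

    def test_allele_flip_inverts_dosage(self):
        # GWAS effect allele is the genotype's other allele: dosage 2 -> 0
        rng = np.random.default_rng(1)
        g = random_genotypes(rng, 3, 1)
        g.dosages[:, 0] = [2.0, 1.0, 0.0]
        ss = SumStats(pd.DataFrame(
            {"id": ["rs0"], "chrom": "1", "bp": [1000],
             "a1": [g.snps.loc[0, "a2"]], "a2": [g.snps.loc[0, "a1"]],
             "beta": [0.5], "se": [0.1], "p": [0.5]}
        ))
        assert np.allclose(score(g, ss, ["rs0"]), [0.0, 0.5, 1.0])

    def test_palindromic_snp_dropped(self):
        rng = np.random.default_rng(2)
        g = random_genotypes(rng, 5, 1)
        g.snps.loc[0, ["a1", "a2"]] = ["A", "T"]
        ss = SumStats(pd.DataFrame(
            {"id": ["rs0"], "chrom": "1", "bp": [1000], "a1": ["A"], "a2": ["T"],
             "beta": [1.0], "se": [0.1], "p": [0.5]}
        ))
        assert np.allclose(score(g, ss, ["rs0"]), 0)

    def test_irreconcilable_alleles_dropped(self):
        rng = np.random.default_rng(3)
        g = random_genotypes(rng, 5, 1)  # genotype alleles A/G
        ss = SumStats(pd.DataFrame(
            {"id": ["rs0"], "chrom": "1", "bp": [1000], "a1": ["T"], "a2": ["C"],
             "beta": [1.0], "se": [0.1], "p": [0.5]}
        ))
        assert np.allclose(score(g, ss, ["rs0"]), 0)

    def test_missing_imputed_as_twice_allele_frequency(self):
        snps = pd.DataFrame(
            {"id": ["rs0"], "chrom": "1", "bp": [100], "a1": ["A"], "a2": ["G"]}
        )
        g = type(random_genotypes(np.random.default_rng(0), 1, 1))(
            individuals=list("abcd"), snps=snps,
            dosages=np.array([[0.0], [2.0], [1.0], [np.nan]]),
        )
        ss = SumStats(pd.DataFrame(
            {"id": ["rs0"], "chrom": "1", "bp": [100], "a1": ["A"], "a2": ["G"],
             "beta": [1.0], "se": [0.1], "p": [0.5]}
        ))
        s = score(g, ss, ["rs0"])
        assert s[3] == pytest.approx(2 * (3 / 6))  # EAF = mean(0,2,1)/2 = 0.5

    def test_scale_equivariance(self):
        rng = np.random.default_rng(4)
        g = random_genotypes(rng, 30, 10)
        betas = rng.normal(0, 0.2, 10)
        ss1 = sumstats_for(g, rng, betas=betas)
        ss2 = SumStats(ss1.table.assign(beta=3.0 * ss1.table["beta"]))
        ids = list(g.snps["id"])
        assert np.allclose(3.0 * score(g, ss1, ids), score(g, ss2, ids))


class TestScoreMatrix:
    def _setup(self, seed=0, n=40, m=15):
        rng = np.random.default_rng(seed)
        g = random_genotypes(rng, n, m, bp_step=100_000)
        ss = sumstats_for(g, rng)
        return g, ss, list(g.snps["id"])

    def test_single_threshold_equals_plain_score(self):
        g, ss, ids = self._setup()
        sm = score_matrix(g, ss, ids, ThresholdGrid(np.array([1.0])),
                          standardize=False)
        assert np.allclose(sm.scores[:, 0], score(g, ss, ids))

    def test_threshold_membership(self):
        g, ss, ids = self._setup(m=2)
        ss.table.loc[:, "p"] = [1e-9, 0.01]
        grid = ThresholdGrid(np.array([1e-8, 0.05]))
        sm = score_matrix(g, ss, ids, grid, standardize=False)
        assert list(sm.snp_counts) == [1, 2]

    def test_columns_match_bruteforce_subsets(self):
        g, ss, ids = self._setup(seed=5)
        grid = ThresholdGrid(np.array([1e-4, 0.05, 0.3, 1.0]))
        sm = score_matrix(g, ss, ids, grid, standardize=False)
        for k, t in enumerate(grid.thresholds):
            subset = ss.table.loc[ss.table["p"] <= t, "id"].tolist()
            assert np.allclose(sm.scores[:, k], score(g, ss, subset), atol=1e-12)

    def test_nestedness_and_monotone_counts(self):
        g, ss, ids = self._setup(seed=6)
        grid = ThresholdGrid(np.geomspace(1e-6, 1.0, 12))
        sm = score_matrix(g, ss, ids, grid)
        assert (np.diff(sm.snp_counts) >= 0).all()

    def test_standardized_columns(self):
        g, ss, ids = self._setup(seed=7)
        grid = ThresholdGrid(np.array([0.5, 1.0]))
        sm = score_matrix(g, ss, ids, grid, standardize=True)
        ok = ~sm.degenerate
        assert np.allclose(sm.scores[:, ok].mean(axis=0), 0, atol=1e-8)
        assert np.allclose(sm.scores[:, ok].std(axis=0), 1, atol=1e-8)

    def test_empty_columns_flagged_degenerate(self):
        g, ss, ids = self._setup(seed=8)
        ss.table.loc[:, "p"] = 0.5
        grid = ThresholdGrid(np.array([1e-8, 1.0]))
        sm = score_matrix(g, ss, ids, grid)
        assert sm.degenerate[0] and not sm.degenerate[1]
        assert np.allclose(sm.scores[:, 0], 0)


def _toy_score_matrix(rng, n=200, k=8, nested=True):
    contrib = rng.standard_normal((n, k))
    scores = np.cumsum(contrib, axis=1) if nested else contrib
    scores = (scores - scores.mean(0)) / scores.std(0)
    return ScoreMatrix(
        individuals=[f"i{i}" for i in range(n)],
        thresholds=ThresholdGrid(np.linspace(0.01, 1.0, k)),
        scores=scores,
        snp_counts=np.arange(1, k + 1),
        standardized=True,
    )


class TestSelectThreshold:
    def test_single_threshold_grid(self):
        rng = np.random.default_rng(0)
        sm = _toy_score_matrix(rng, k=1)
        sel = select_threshold(sm, rng.standard_normal(200), B=19, seed=1)
        assert sel.best_threshold == sm.thresholds.thresholds[0]

    def test_recovers_constructed_optimum(self):
        rng = np.random.default_rng(1)
        sm = _toy_score_matrix(rng, nested=False)
        y = 2.0 * sm.scores[:, 4]  # exact linear function of column 4
        sel = select_threshold(sm, y, B=0)
        assert sel.best_threshold == sm.thresholds.thresholds[4]

    def test_constant_phenotype_raises(self):
        rng = np.random.default_rng(2)
        sm = _toy_score_matrix(rng)
        with pytest.raises(ValueError, match="constant"):
            select_threshold(sm, np.ones(200), B=0)

    def test_statistic_matches_statsmodels_wald_t(self):
        # dual route: fast residual-projection t vs explicit OLS per column
        rng = np.random.default_rng(3)
        sm = _toy_score_matrix(rng)
        y = rng.standard_normal(200) + 0.2 * sm.scores[:, 3]
        covar = rng.standard_normal((200, 2))
        sel = select_threshold(sm, y, covariates=covar, B=0)
        for k in range(len(sm.thresholds)):
            X = np.column_stack([np.ones(200), sm.scores[:, k], covar])
            fit = smapi.OLS(y, X).fit()
            assert sel.statistics[k] == pytest.approx(
                abs(fit.tvalues[1]), rel=1e-8
            )

    def test_empirical_p_bounds_and_determinism(self):
        rng = np.random.default_rng(4)
        sm = _toy_score_matrix(rng)
        y = rng.standard_normal(200)
        a = select_threshold(sm, y, B=99, seed=7)
        b = select_threshold(sm, y, B=99, seed=7)
        assert a.empirical_p == b.empirical_p
        assert 1 / 100 <= a.empirical_p <= 1.0

    def test_binary_family_uses_logistic(self):
        rng = np.random.default_rng(5)
        sm = _toy_score_matrix(rng, n=300)
        logits = 1.5 * sm.scores[:, 2]
        y = (rng.random(300) < 1 / (1 + np.exp(-logits))).astype(float)
        sel = select_threshold(sm, y, B=0, family="auto")
        assert sel.best_threshold == sm.thresholds.thresholds[2]
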