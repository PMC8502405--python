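"""Effect-size concordance regressions and the detection-rate enrichment test."""

import numpy as np
import pytest
from scipy import stats

from iehc.concordance import (
    EffectPair,
    TwoByTwoCounts,
    concordance_study,
    enrichment_test,
    gene_regression,
    marginal_cox_effects,
)
from iehc.cox import SurvivalDataset
from iehc.pipeline import GenotypeMatrix
from iehc.simulate import simulate_genotypes, simulate_survival


class TestGeneRegression:
    def test_perfect_linear_fit(self):
        x = np.array([0.1, -0.2, 0.4, 0.0, 0.3])
        res = gene_regression(EffectPair("g", 2.0 * x, x))
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.p_value < 1e-6

    def test_orthogonal_residual(self):
        x = np.array([1.0, -1.0, 2.0, -2.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # constructed orthogonal to x
        assert x @ y == 0
        res = gene_regression(EffectPair("g", y - y.mean(), x))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        x = rng.standard_normal(12)
        y = 0.7 * x + rng.standard_normal(12) * 0.3
        res = gene_regression(EffectPair("g", y, x))
        # closed-form OLS via the normal equations
        X = np.column_stack([np.ones_like(x), x])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.slope == pytest.approx(coef[1], abs=1e-10)
        r = np.corrcoef(x, y)[0, 1]
        assert res.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_zero_variance_covariate_flagged(self):
        res = gene_regression(EffectPair("g", np.array([1.0, 2.0, 3.0]),
                                         np.zeros(3)))
        assert res.undefined_slope

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValueError):
            EffectPair("g", np.array([1.0, 2.0]), np.array([0.1, 0.2]))

    def test_study_fdr_attached(self, rng):
        pairs = []
        for k in range(6):
            x = rng.standard_normal(10)
            y = (1.0 if k < 3 else 0.0) * x + rng.standard_normal(10) * 0.2
            pairs.append(EffectPair(f"g{k}", y, x))
        results = concordance_study(pairs)
        qs = [r.q_value for r in results]
        assert all(np.isfinite(qs))
        assert all(r.q_value >= r.p_value - 1e-15 for r in results)


class TestMarginalCox:
    def test_null_snp_near_zero(self, rng):
        G2 = simulate_genotypes(400, 4, np.full(4, 0.3), 0.3, rng)
        time, status, X1, X2 = simulate_survival(G2, np.zeros(4), rng=rng)
        pheno = SurvivalDataset(subject_id=np.arange(400), time=time, status=status,
                                covariates=np.column_stack([X1, X2]))
        G = GenotypeMatrix(sample_ids=np.arange(400),
                           snp_ids=np.array([f"s{j}" for j in range(4)], dtype=object),
                           dosages=G2)
        eff = marginal_cox_effects(G, pheno)
        assert np.isfinite(eff).all()
        assert np.all(np.abs(eff) < 0.5)

    def test_effect_recovery(self, rng):
        """A SNP with true marginal log-hazard 0.3 is recovered within its CI."""
        n = 2000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        rate = 0.05 * np.exp(0.3 * g)
        T = rng.exponential(1.0 / rate)
        C = rng.exponential(np.median(T) / np.log(2))
        pheno = SurvivalDataset(subject_id=np.arange(n), time=np.minimum(T, C),
                                status=(T <= C).astype(int),
                                covariates=np.empty((n, 0)))
        G = GenotypeMatrix(sample_ids=np.arange(n),
                           snp_ids=np.array(["s0"], dtype=object),
                           dosages=g[:, None])
        eff = marginal_cox_effects(G, pheno)
        assert eff[0] == pytest.approx(0.3, abs=0.12)

    def test_monomorphic_snp_missing(self, rng):
        n = 100
        g = np.column_stack([np.ones(n), rng.integers(0, 3, n).astype(float)])
        T = rng.exponential(10, n)
        pheno = SurvivalDataset(subject_id=np.arange(n), time=T,
                                status=np.ones(n, dtype=int),
                                covariates=np.empty((n, 0)))
        G = GenotypeMatrix(sample_ids=np.arange(n),
                           snp_ids=np.array(["mono", "poly"], dtype=object),
                           dosages=g)
        eff = marginal_cox_effects(G, pheno)
        assert np.isnan(eff[0]) and np.isfinite(eff[1])


class TestEnrichment:
    def test_identical_rates_give_zero(self):
        stat, p, ratio = enrichment_test(TwoByTwoCounts(10, 90, 10, 90))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert ratio == pytest.approx(1.0)

    def test_hand_computed_with_correction(self):
        """(20,80 | 10,90): expected 15/85; corrected chi-square ~ 3.18."""
        stat, p, ratio = enrichment_test(TwoByTwoCounts(20, 80, 10, 90))
        assert stat == pytest.approx(3.18, abs=0.01)
        assert p == pytest.approx(0.0747, abs=5e-4)
        assert ratio == pytest.approx(2.0)

    def test_row_swap_inverts_ratio(self):
        s1, p1, r1 = enrichment_test(TwoByTwoCounts(30, 70, 12, 88))
        s2, p2, r2 = enrichment_test(TwoByTwoCounts(12, 88, 30, 70))
        assert s1 == pytest.approx(s2)
        assert p1 == pytest.approx(p2)
        assert r1 == pytest.approx(1.0 / r2)

    def test_zero_margin_untestable(self):
        stat, p, _ = enrichment_test(TwoByTwoCounts(0, 0, 5, 95))
        assert np.isnan(stat) and np.isnan(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoCounts(-1, 2, 3, 4)


class TestNullConcordance:
    def test_no_false_concordance_under_independence(self, rng):
        """Survival independent of genotypes: ~no genes reach q < 0.05."""
        n_genes, hits = 40, 0
        for k in range(n_genes):
            x = rng.standard_normal(8)   # eQTL effects
            y = rng.standard_normal(8)   # independent survival effects
            hits += gene_regression(EffectPair(f"g{k}", y, x)).p_value < 0.05 / n_genes
        assert hits == 0
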