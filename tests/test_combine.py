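"""The three joint-test combiners and the ACAT omnibus."""

import numpy as np
import pytest
from scipy import stats

from iehc.combine import (
    acat_combine,
    adapt_combine,
    fisher_combine,
    optim_combine,
)
from iehc.kernel import KernelScoreResult


def _km(q, lam):
    return KernelScoreResult(Q=q, eigenvalues=np.asarray(lam, dtype=float),
                             p_value=0.5, tail_method="davies")


class TestFisher:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [(1.0, 1.0, 1.0), (0.05, 0.05, 0.01748), (0.5, 0.5, 0.5966)],
    )
    def test_examples(self, p1, p2, expected):
        assert fisher_combine(p1, p2) == pytest.approx(expected, abs=5e-5)

    def test_closed_form(self, rng):
        """Matches exp(-T/2)(1 + T/2), the 4-df chi-square upper tail."""
        for _ in range(50):
            p1, p2 = rng.uniform(1e-6, 1, size=2)
            T = -2 * (np.log(p1) + np.log(p2))
            assert fisher_combine(p1, p2) == pytest.approx(
                np.exp(-T / 2) * (1 + T / 2), rel=1e-12)

    def test_zero_input_clamped(self):
        p = fisher_combine(0.0, 0.5)
        assert 0 < p < 1e-100


class TestAdapt:
    def test_both_one(self):
        assert adapt_combine(1.0, 1.0) == 1.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(1e-4, 1, size=2)
            assert adapt_combine(a, b) == adapt_combine(b, a)

    def test_against_monte_carlo(self, rng):
        """Exact integration matches the min-p null simulated from uniforms."""
        n = 10**7
        u1 = rng.uniform(size=n)
        u2 = rng.uniform(size=n)
        pf = stats.chi2.sf(-2 * (np.log(u1) + np.log(u2)), 4)
        m = np.minimum(np.minimum(u1, u2), pf)
        for pair in [(0.05, 0.5), (0.3, 0.4), (0.01, 0.9)]:
            pfo = stats.chi2.sf(-2 * np.log(pair[0] * pair[1]), 4)
            mo = min(*pair, pfo)
            emp = (m <= mo).mean()
            se = np.sqrt(emp * (1 - emp) / n)
            assert abs(adapt_combine(*pair) - emp) <= 3 * se


class TestOptim:
    def test_grid_of_one_reduces_to_burden(self):
        km = _km(5.0, [1.0, 0.5])
        p, rho = optim_combine(3.8415, km, rho_grid=(1.0,))
        assert rho == 1.0
        assert p == pytest.approx(stats.chi2.sf(3.8415, 1), rel=1e-6)

    def test_grid_of_zero_reduces_to_km(self):
        from iehc.kernel import davies_pvalue

        km = _km(5.0, [1.0, 0.5])
        p, rho = optim_combine(3.8415, km, rho_grid=(0.0,))
        assert rho == 0.0
        assert p == pytest.approx(davies_pvalue(5.0, km.eigenvalues)[0], rel=1e-6)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            optim_combine(1.0, _km(1.0, [1.0]), rho_grid=())

    def test_against_monte_carlo(self, rng):
        """Integration p matches simulation of independent (U_theta, U_tau)."""
        from iehc.kernel import _mixture_quantile_fast, _mixture_sf_many

        lam = np.sort(rng.uniform(0.2, 5.0, size=12))[::-1]
        grid = (0.0, 0.01, 0.04, 0.09, 0.25, 0.5, 1.0)
        n = 10**6
        U = rng.chisquare(1, n)
        V = rng.chisquare(1, (n, lam.size)) @ lam
        for u_th, u_ta in [(3.0, 20.0), (0.5, 8.0), (6.0, 40.0)]:
            p_an, _ = optim_combine(u_th, _km(u_ta, lam), grid)
            p_obs = []
            for r in grid:
                eig = np.concatenate(([r] if r > 0 else [], (1 - r) * lam if r < 1 else []))
                p_obs.append(_mixture_sf_many(
                    np.array([r * u_th + (1 - r) * u_ta]), eig)[0])
            minp = min(p_obs)
            rej = np.zeros(n, dtype=bool)
            for r in grid:
                eig = np.concatenate(([r] if r > 0 else [], (1 - r) * lam if r < 1 else []))
                rej |= r * U + (1 - r) * V >= _mixture_quantile_fast(minp, eig)
            emp = rej.mean()
            se = np.sqrt(emp * (1 - emp) / n)
            assert abs(p_an - emp) <= 3 * se

    def test_ties_select_smallest_rho(self):
        # with a unit rank-1 kernel and U_theta = U_tau the two endpoints
        # give identical mixtures, so the tie must resolve to rho = 0
        km = _km(2.0, [1.0])
        _, rho = optim_combine(2.0, km, rho_grid=(0.0, 1.0))
        assert rho == 0.0


class TestACAT:
    def test_all_half(self):
        assert acat_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_identity_on_equal_ps(self, rng):
        for p in rng.uniform(1e-4, 1 - 1e-4, size=10):
            assert acat_combine([p, p, p, p]) == pytest.approx(p, rel=1e-8)

    def test_two_value_example(self):
        assert acat_combine([0.01, 0.5]) == pytest.approx(0.0200, abs=5e-4)

    def test_tiny_p_asymptote(self):
        p = acat_combine([1e-20, 0.5])
        assert p == pytest.approx(2e-20, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            acat_combine([])
        with pytest.raises(ValueError):
            acat_combine([0.5], weights=[0.0])
        with pytest.raises(ValueError):
            acat_combine([0.0, 0.5])


class TestCombinerProperties:
    def test_monotone_in_each_argument(self):
        """Combined p never increases when an input p decreases."""
        grid = np.array([0.9, 0.5, 0.2, 0.05, 0.01, 0.001])
        for comb in (fisher_combine, adapt_combine):
            for fixed in (0.8, 0.3, 0.02):
                vals = [comb(p, fixed) for p in grid]
                assert np.all(np.diff(vals) <= 1e-12)
        vals = [acat_combine([p, 0.3]) for p in grid]
        assert np.all(np.diff(vals) <= 1e-12)

    def test_null_uniformity_smoke(self, rng):
        """On independent uniforms each combiner's output stays uniform."""
        n = 1500
        u = rng.uniform(size=(n, 2))
        for comb in (fisher_combine, adapt_combine):
            out = np.array([comb(a, b) for a, b in u])
            assert stats.kstest(out, "uniform").pvalue > 0.01
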