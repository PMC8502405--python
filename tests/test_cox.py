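"""Cox engine: analytic solutions, oracle cross-checks, degeneracy handling."""

import numpy as np
import pytest
from scipy import stats

from iehc.cox import (
    DegenerateDesignError,
    DegenerateVarianceError,
    NoEventsError,
    SurvivalDataset,
    fit_cox,
    information_operator,
    wald_test,
)
from tests.conftest import make_survival


class TestFitCox:
    def test_analytic_single_covariate(self, three_subject_data):
        """Score equation u/(u+2) + u/(u+1) = 1 has root u = sqrt(2)."""
        fit = fit_cox(three_subject_data, np.array([[0.0], [1.0], [0.0]]))
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(0.5 * np.log(2.0), abs=1e-6)

    def test_wald_matches_numerical_hessian(self, three_subject_data):
        """Coefficient variance equals the inverse numerical Hessian at the optimum."""
        Z = np.array([[0.0], [1.0], [0.0]])
        fit = fit_cox(three_subject_data, Z)

        def logpl(b):
            u = np.exp(b)
            return b - np.log(u + 2.0) - np.log(u + 1.0)

        h = 1e-5
        b0 = fit.coefficients[0]
        hess = (logpl(b0 + h) - 2 * logpl(b0) + logpl(b0 - h)) / h**2
        stat, p = wald_test(fit, 0)
        assert stat == pytest.approx(b0**2 * (-hess), abs=1e-6)
        assert 0 < p <= 1

    def test_constant_column_rejected(self, three_subject_data):
        with pytest.raises(DegenerateDesignError):
            fit_cox(three_subject_data, np.ones((3, 1)))

    def test_collinear_design_rejected(self, rng):
        data = make_survival(rng, n=60, n_cov=1)
        Z = np.column_stack([data.covariates[:, 0], 2 * data.covariates[:, 0]])
        with pytest.raises(DegenerateDesignError):
            fit_cox(data, Z)

    def test_zero_events_rejected(self):
        with pytest.raises(NoEventsError):
            SurvivalDataset(subject_id=[1, 2], time=[1.0, 2.0], status=[0, 0],
                            covariates=np.empty((2, 0)))

    def test_null_model_residuals_sum_to_zero(self, rng):
        data = make_survival(rng, n=80, n_cov=0)
        fit = fit_cox(data, None)
        assert fit.martingale_residuals.sum() == pytest.approx(0.0, abs=1e-10)
        assert np.all(fit.martingale_residuals <= 1.0 + 1e-12)

    def test_fitted_model_residuals_sum_to_zero(self, rng):
        data = make_survival(rng, n=120, n_cov=3, beta=[0.3, -0.2, 0.0])
        fit = fit_cox(data, data.covariates)
        assert fit.martingale_residuals.sum() == pytest.approx(0.0, abs=1e-9)

    def test_loglik_improves_over_zero(self, rng):
        data = make_survival(rng, n=100, n_cov=2, beta=[0.5, 0.0])
        fit = fit_cox(data, data.covariates)
        null = fit_cox(data, None)
        assert fit.log_partial_likelihood >= null.log_partial_likelihood - 1e-12

    def test_breslow_equals_efron_without_ties(self, rng):
        data = make_survival(rng, n=90, n_cov=2, beta=[0.4, -0.3])
        assert np.unique(data.time).size == data.n  # continuous times: no ties
        fe = fit_cox(data, data.covariates, ties="efron")
        fb = fit_cox(data, data.covariates, ties="breslow")
        assert np.max(np.abs(fe.coefficients - fb.coefficients)) < 1e-10

    def test_covariance_symmetric_psd(self, rng):
        data = make_survival(rng, n=150, n_cov=3, beta=[0.2, 0.1, -0.4])
        fit = fit_cox(data, data.covariates)
        C = fit.coefficient_covariance
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() > 0

    def test_estimate_recovery_coverage(self):
        """95% Wald CI covers the true log-hazard ratio in >=90% of replicates."""
        rng = np.random.default_rng(7)
        true = 0.5
        hits = 0
        reps = 100
        for _ in range(reps):
            n = 5000
            x = rng.standard_normal(n)
            T = rng.exponential(1.0 / (0.1 * np.exp(true * x)))
            C = rng.exponential(np.median(T) / np.log(2))  # ~50% censoring
            time = np.minimum(T, C)
            status = (T <= C).astype(int)
            data = SurvivalDataset(subject_id=np.arange(n), time=time,
                                   status=status, covariates=x[:, None])
            fit = fit_cox(data, data.covariates)
            se = np.sqrt(fit.coefficient_covariance[0, 0])
            hits += abs(fit.coefficients[0] - true) <= 1.96 * se
        assert hits >= 0.90 * reps


class TestAgainstLifelines:
    """Independent oracle: lifelines CoxPHFitter on the same data."""

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_coefficients_and_se(self, rng, ties):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        data = make_survival(rng, n=200, n_cov=3, beta=[0.5, -0.3, 0.0])
        # introduce tied event times to exercise the tie corrections
        t = np.round(data.time, 1) + 0.05
        data = SurvivalDataset(subject_id=data.subject_id, time=t,
                               status=data.status, covariates=data.covariates)
        fit = fit_cox(data, data.covariates, ties=ties)
        df = pd.DataFrame(data.covariates, columns=["a", "b", "c"])
        df["T"] = data.time
        df["E"] = data.status
        cph = lifelines.CoxPHFitter()
        cph.fit(df, "T", "E")  # lifelines uses Efron ties
        if ties == "efron":
            assert np.allclose(fit.coefficients, cph.params_.to_numpy(), atol=1e-5)
            ses = np.sqrt(np.diag(fit.coefficient_covariance))
            assert np.allclose(ses, cph.standard_errors_.to_numpy(), atol=1e-5)
        else:
            # Breslow differs from Efron under ties but only mildly
            assert np.allclose(fit.coefficients, cph.params_.to_numpy(), atol=0.05)


class TestWald:
    def test_zero_coefficient_gives_p_one(self):
        from iehc.cox import CoxFit

        fit = CoxFit(coefficients=np.array([0.0]),
                     coefficient_covariance=np.array([[2.0]]),
                     log_partial_likelihood=0.0, linear_predictor=np.zeros(3),
                     baseline_times=np.empty(0), baseline_cumhaz=np.empty(0),
                     martingale_residuals=np.zeros(3), converged=True, n_iterations=1)
        stat, p = wald_test(fit, 0)
        assert stat == 0.0 and p == 1.0

    def test_known_quantile(self):
        from iehc.cox import CoxFit

        fit = CoxFit(coefficients=np.array([1.96]),
                     coefficient_covariance=np.array([[1.0]]),
                     log_partial_likelihood=0.0, linear_predictor=np.zeros(3),
                     baseline_times=np.empty(0), baseline_cumhaz=np.empty(0),
                     martingale_residuals=np.zeros(3), converged=True, n_iterations=1)
        stat, p = wald_test(fit, 0)
        assert stat == pytest.approx(3.8416)
        assert p == pytest.approx(0.0500, abs=5e-4)

    def test_degenerate_variance(self):
        from iehc.cox import CoxFit

        fit = CoxFit(coefficients=np.array([1.0]),
                     coefficient_covariance=np.array([[0.0]]),
                     log_partial_likelihood=0.0, linear_predictor=np.zeros(3),
                     baseline_times=np.empty(0), baseline_cumhaz=np.empty(0),
                     martingale_residuals=np.zeros(3), converged=True, n_iterations=1)
        with pytest.raises(DegenerateVarianceError):
            wald_test(fit, 0)


class TestInformationOperator:
    def test_matches_numerical_hessian_in_eta(self, rng):
        """V equals the finite-difference negative Hessian of the log PL in eta."""
        n = 12
        data = make_survival(rng, n=n, n_cov=1)
        eta = rng.standard_normal(n) * 0.5

        def logpl(e):
            # Breslow log PL in eta, brute force
            ll = 0.0
            for i in range(n):
                if data.status[i]:
                    risk = data.time >= data.time[i]
                    ll += e[i] - np.log(np.exp(e[risk]).sum())
            return ll

        V = information_operator(data.time, data.status, eta, "breslow")
        h = 1e-5
        H = np.zeros((n, n))
        for a in range(n):
            for b in range(n):
                ep = eta.copy(); ep[a] += h; ep[b] += h
                em = eta.copy(); em[a] += h; em[b] -= h
                fp = eta.copy(); fp[a] -= h; fp[b] += h
                fm = eta.copy(); fm[a] -= h; fm[b] -= h
                H[a, b] = (logpl(ep) - logpl(em) - logpl(fp) + logpl(fm)) / (4 * h**2)
        assert np.allclose(V, -H, atol=1e-4)

    def test_rows_sum_to_zero(self, rng):
        """V annihilates constants (the PL is shift-invariant in eta)."""
        data = make_survival(rng, n=50, n_cov=1)
        eta = rng.standard_normal(50) * 0.3
        V = information_operator(data.time, data.status, eta, "efron")
        assert np.allclose(V @ np.ones(50), 0.0, atol=1e-10)

    def test_tie_path_matches_loop_free_path(self, rng):
        """With no ties the Efron loop and the vectorised Breslow form agree."""
        data = make_survival(rng, n=40, n_cov=1)
        eta = rng.standard_normal(40) * 0.2
        Vb = information_operator(data.time, data.status, eta, "breslow")
        Ve = information_operator(data.time, data.status, eta, "efron")
        assert np.allclose(Vb, Ve, atol=1e-12)
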