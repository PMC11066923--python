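"""Unit tests for the ZINB likelihood primitives and EM block updates."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize
from scipy.special import expit, logit

import statsmodels.api as sm

from mbdecoda import (
    AbundanceTable,
    CovariateSet,
    EMControl,
    ModelError,
    ZINBParams,
    e_step,
    fit_em,
    m_step_nb_samples,
    m_step_nb_taxa,
    m_step_zero,
    nb_logpmf,
    zinb_marginal_loglik,
)


def _params(n, K, d=0.0, Delta=0.0, beta0=1.0, alpha0=0.0, phi=1.0):
    return ZINBParams(
        d=np.full(n, float(d)),
        Delta=np.full(K, float(Delta)),
        beta=np.full((K, 1), float(beta0)),
        alpha=np.full((K, 1), float(alpha0)),
        phi=np.full(K, float(phi)),
    )


def _binary_x(n):
    return np.r_[np.zeros(n // 2), np.ones(n - n // 2)]


class TestNBLogpmf:
    @pytest.mark.parametrize(
        "y, mu, phi, expected",
        [
            (0, 1.0, 1.0, np.log(0.5)),  # (phi/(mu+phi))^phi
            (2, 2.0, 2.0, np.log(0.1875)),  # Gamma(4)/(Gamma(2) 2!) (1/2)^2 (1/2)^2
        ],
    )
    def test_closed_forms(self, y, mu, phi, expected):
        assert nb_logpmf(y, mu, phi) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_small_mean(self):
        # as mu -> 0 the zero count becomes certain
        assert nb_logpmf(0, 1e-12, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_matches_scipy_parameterization(self, rng):
        y = rng.integers(0, 200, size=50)
        mu = rng.uniform(0.1, 500.0, size=50)
        phi = rng.uniform(0.05, 50.0, size=50)
        ours = nb_logpmf(y, mu, phi)
        ref = stats.nbinom.logpmf(y, phi, phi / (mu + phi))
        np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_log_scale_is_overflow_safe(self):
        val = nb_logpmf(10**6, 1e5, 1e5)
        assert np.isfinite(val)

    @pytest.mark.parametrize(
        "y, mu, phi", [(1, -1.0, 1.0), (1, 1.0, 0.0), (-1, 1.0, 1.0), (1.5, 1.0, 1.0)]
    )
    def test_invalid_arguments(self, y, mu, phi):
        with pytest.raises(ModelError):
            nb_logpmf(y, mu, phi)


class TestMarginalLoglik:
    def test_no_inflation_reduces_to_nb(self, rng):
        n, K = 12, 4
        y = rng.integers(0, 30, size=(n, K))
        y[0] += 1  # keep totals positive
        table = AbundanceTable(y)
        cov = CovariateSet(X=_binary_x(n))
        params = _params(n, K, beta0=2.0, alpha0=-40.0, phi=2.0)  # eta ~ 0
        ll = zinb_marginal_loglik(table, cov, params)
        mu = np.exp(params.d[:, None] + cov.X[:, None] * params.Delta + params.beta[:, 0])
        direct = nb_logpmf(y, mu, params.phi[None, :]).sum()
        assert ll == pytest.approx(direct, rel=1e-9)

    def test_single_zero_cell_mixture(self):
        # eta=0.5, mu=1, phi=1 at y=0: log(0.5 + 0.5 * 0.5)
        table = AbundanceTable(np.array([[0], [1]]), allow_empty_samples=True)
        cov = CovariateSet(X=np.array([0.0, 1.0]))
        params = ZINBParams(
            d=np.zeros(2),
            Delta=np.zeros(1),
            beta=np.zeros((1, 1)),
            alpha=np.zeros((1, 1)),  # eta = 0.5
            phi=np.ones(1),
        )
        ll = zinb_marginal_loglik(table, cov, params)
        expected = np.log(0.75) + np.log(0.5) + nb_logpmf(1, 1.0, 1.0)
        assert ll == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch_rejected(self):
        table = AbundanceTable(np.ones((4, 2), dtype=int))
        cov = CovariateSet(X=_binary_x(4))
        with pytest.raises(ModelError):
            zinb_marginal_loglik(table, cov, _params(5, 2))


class TestEStep:
    def test_positive_counts_have_zero_posterior(self):
        y = np.array([[3, 0], [1, 2], [0, 5], [2, 1]])
        table = AbundanceTable(y)
        cov = CovariateSet(X=_binary_x(4))
        z = e_step(table, cov, _params(4, 2, alpha0=0.5, phi=2.0))
        assert np.all(z[y > 0] == 0.0)
        assert np.all((z >= 0) & (z <= 1))

    def test_no_inflation_gives_zero_posterior(self):
        table = AbundanceTable(np.array([[0, 1], [1, 0]]))
        cov = CovariateSet(X=np.array([0.0, 1.0]))
        z = e_step(table, cov, _params(2, 2, alpha0=-60.0))
        np.testing.assert_allclose(z, 0.0, atol=1e-20)

    def test_posterior_closed_form(self):
        # eta=0.5, mu=1, phi=1, y=0: z = 0.5 / (0.5 + 0.5*0.5) = 2/3
        table = AbundanceTable(np.array([[0], [1]]), allow_empty_samples=True)
        cov = CovariateSet(X=np.array([0.0, 1.0]))
        z = e_step(table, cov, _params(2, 1, alpha0=0.0, beta0=0.0, phi=1.0))
        assert z[0, 0] == pytest.approx(2.0 / 3.0, rel=1e-12)


class TestMStepZero:
    def test_intercept_only_closed_form(self):
        n = 10
        cov = CovariateSet(X=_binary_x(n))
        z = np.column_stack([np.full(n, 0.3), np.full(n, 0.8)])
        alpha = m_step_zero(z, cov)
        np.testing.assert_allclose(alpha[:, 0], logit([0.3, 0.8]), rtol=1e-10)

    def test_degenerate_all_zero_posteriors_clamped(self):
        n = 8
        cov = CovariateSet(X=_binary_x(n))
        alpha = m_step_zero(np.zeros((n, 1)), cov)
        assert alpha[0, 0] == pytest.approx(logit(1e-6))

    def test_covariate_fit_matches_generic_optimizer(self, rng):
        n = 40
        U = np.column_stack([np.ones(n), rng.standard_normal(n)])
        cov = CovariateSet(X=_binary_x(n), U=U)
        z = rng.uniform(0.05, 0.95, size=(n, 1))
        alpha = m_step_zero(z, cov)

        def negq(a):
            eta = np.clip(expit(U @ a), 1e-12, 1 - 1e-12)
            return -(z[:, 0] * np.log(eta) + (1 - z[:, 0]) * np.log(1 - eta)).sum()

        ref = minimize(negq, np.zeros(2), method="BFGS").fun
        assert negq(alpha[0]) <= ref + 1e-6


class TestMStepNBTaxa:
    def test_single_taxon_matches_direct_mle(self, rng):
        n = 120
        x = _binary_x(n)
        mu = np.exp(2.0 + 0.7 * x)
        y = rng.negative_binomial(3.0, 3.0 / (mu + 3.0))
        table = AbundanceTable(y[:, None], allow_empty_samples=True)
        cov = CovariateSet(X=x)
        Delta, beta, phi, conv = m_step_nb_taxa(
            table, cov, np.zeros((n, 1)), d=np.zeros(n)
        )

        def nll(p):
            m = np.exp(p[1] + x * p[0])
            return -nb_logpmf(y, m, np.exp(p[2])).sum()

        ref = minimize(
            nll, np.array([0.5, 2.0, 0.5]), method="Nelder-Mead",
            options=dict(xatol=1e-10, fatol=1e-12, maxfev=20000),
        )
        assert Delta[0] == pytest.approx(ref.x[0], abs=1e-3)
        assert beta[0, 0] == pytest.approx(ref.x[1], abs=1e-3)
        assert phi[0] == pytest.approx(np.exp(ref.x[2]), abs=1e-3 * np.exp(ref.x[2]))

    def test_poisson_limit_recovers_poisson_glm(self, rng):
        n = 400
        x = _binary_x(n)
        mu = np.exp(2.5 + 0.5 * x)
        y = rng.poisson(mu)
        table = AbundanceTable(y[:, None], allow_empty_samples=True)
        cov = CovariateSet(X=x)
        Delta, beta, phi, _ = m_step_nb_taxa(table, cov, np.zeros((n, 1)), d=np.zeros(n))
        assert phi[0] > 50
        glm = sm.GLM(y, np.column_stack([x, np.ones(n)]), family=sm.families.Poisson())
        fit = glm.fit()
        assert Delta[0] == pytest.approx(fit.params[0], abs=0.05)
        assert beta[0, 0] == pytest.approx(fit.params[1], abs=0.05)

    def test_no_group_effect_recovers_sample_mean(self, rng):
        # both groups carry identical counts -> Delta ~ 0 and exp(beta0) ~ mean
        half = rng.integers(1, 40, size=30)
        y = np.r_[half, half]
        n = y.size
        table = AbundanceTable(y[:, None], allow_empty_samples=True)
        cov = CovariateSet(X=_binary_x(n))
        Delta, beta, phi, _ = m_step_nb_taxa(table, cov, np.zeros((n, 1)), d=np.zeros(n))
        assert Delta[0] == pytest.approx(0.0, abs=1e-6)
        assert np.exp(beta[0, 0]) == pytest.approx(y.mean(), rel=1e-6)

    def test_unobserved_taxon_rejected(self):
        y = np.column_stack([np.arange(1, 7), np.zeros(6, dtype=int)])
        table = AbundanceTable(y)
        cov = CovariateSet(X=_binary_x(6))
        with pytest.raises(ModelError):
            m_step_nb_taxa(table, cov, np.zeros((6, 2)), d=np.zeros(6))


class TestMStepNBSamples:
    def test_poisson_limit_closed_form(self, rng):
        n, K = 15, 8
        x = _binary_x(n)
        y = rng.integers(1, 60, size=(n, K))
        table = AbundanceTable(y)
        cov = CovariateSet(X=x)
        Delta = rng.normal(0, 0.3, K)
        beta = np.column_stack([rng.normal(2, 0.3, K)])
        phi = np.full(K, 1e7)
        d = m_step_nb_samples(table, cov, np.zeros((n, K)), Delta, beta, phi)
        off = x[:, None] * Delta[None, :] + beta[:, 0][None, :]
        closed = np.log(y.sum(axis=1) / np.exp(off).sum(axis=1))
        np.testing.assert_allclose(d, closed, atol=1e-6)

    def test_doubling_counts_shifts_offset_by_log2(self):
        n, K = 10, 20
        x = _binary_x(n)
        beta = np.full((K, 1), 3.0)
        mu = np.exp(np.full((n, K), 3.0))
        y = np.rint(mu).astype(int)  # expectation-generated counts
        d1 = m_step_nb_samples(
            AbundanceTable(y), CovariateSet(X=x), np.zeros((n, K)),
            np.zeros(K), beta, np.full(K, 3.0),
        )
        y2 = y.copy()
        y2[0] *= 2
        d2 = m_step_nb_samples(
            AbundanceTable(y2), CovariateSet(X=x), np.zeros((n, K)),
            np.zeros(K), beta, np.full(K, 3.0),
        )
        assert d2[0] - d1[0] == pytest.approx(np.log(2), abs=0.01)
        np.testing.assert_allclose(d2[1:], d1[1:], atol=1e-8)

    def test_uninformative_sample_rejected(self):
        table = AbundanceTable(np.ones((4, 3), dtype=int))
        cov = CovariateSet(X=_binary_x(4))
        post = np.zeros((4, 3))
        post[2] = 1.0  # sample 2 carries no NB weight
        with pytest.raises(ModelError):
            m_step_nb_samples(
                table, cov, post, np.zeros(3), np.zeros((3, 1)), np.ones(3)
            )


class TestFitEM:
    def test_posterior_validity_and_monotone_trace(self, zinb_dataset):
        fit = fit_em(zinb_dataset.table, zinb_dataset.cov)
        z = fit.posterior[:, fit.estimable]
        y = zinb_dataset.table.counts[:, fit.estimable]
        assert np.all((z >= 0) & (z <= 1))
        assert np.all(z[y > 0] == 0.0)
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * (np.abs(trace[:-1]) + 1.0))
        assert np.all(fit.se_Delta_tilde[fit.estimable] > 0)

    def test_null_taxa_cluster_around_common_bias(self):
        from mbdecoda import SimulationDesign, simulate

        data = simulate(SimulationDesign(n=200, K=50, pi=0.2, eta=0.3, seed=3))
        fit = fit_em(data.table, data.cov)
        null = ~np.isin(np.arange(50), data.signal_set)
        resid = fit.params.Delta[null] - data.Delta_true[null]
        assert np.std(resid[np.isfinite(resid)]) < 0.3

    def test_all_zero_taxon_excluded_with_warning(self, caplog):
        y = np.array([[5, 0, 2], [3, 0, 1], [4, 0, 7], [6, 0, 2]])
        table = AbundanceTable(y)
        cov = CovariateSet(X=_binary_x(4))
        with caplog.at_level("WARNING", logger="mbdecoda.model"):
            fit = fit_em(table, cov)
        assert fit.taxon_ids == ["T1", "T3"]
        assert any("all-zero" in r.message for r in caplog.records)

    def test_offset_shift_absorbed_by_d(self, rng):
        # adding a constant to every generating offset leaves Delta_tilde
        # unchanged up to Monte-Carlo noise
        n, K = 100, 40
        x = _binary_x(n)
        beta0 = rng.normal(3.0, 0.5, K)
        d = rng.normal(0.0, 0.5, n)
        cov = CovariateSet(X=x)

        def draw(shift, seed):
            r = np.random.default_rng(seed)
            mu = np.exp((d + shift)[:, None] + beta0[None, :])
            lam = r.gamma(3.0, mu / 3.0)
            return AbundanceTable(r.poisson(lam))

        fit1 = fit_em(draw(0.0, 99), cov)
        fit2 = fit_em(draw(1.5, 99), cov)
        diff = fit2.params.Delta - fit1.params.Delta
        assert abs(np.nanmean(diff)) < 0.15
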