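"""Unit and property tests for the EXNEX / independent posterior machinery."""

import numpy as np
import pytest
from scipy.special import logit

from baskex import (
    BasketData,
    ExnexConfig,
    MCMCSettings,
    exceedance,
    fit_exnex,
    fit_exnex_batch,
    fit_independent,
    nex_prior_params,
)

from oracle import indep_exceed


class TestNexPriorParams:
    @pytest.mark.parametrize(
        "rho, m_expected, v2_expected",
        [
            (0.5, 0.0, 4.0),
            (0.3, np.log(3 / 7), 1 / 0.3 + 1 / 0.7),
            (0.2, np.log(0.25), 6.25),
        ],
    )
    def test_moment_formulas(self, rho, m_expected, v2_expected):
        prior = nex_prior_params(rho)
        assert prior.m[0] == pytest.approx(m_expected, abs=1e-12)
        assert prior.v2[0] == pytest.approx(v2_expected, abs=1e-12)

    @pytest.mark.parametrize("rho", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_rates_outside_open_interval(self, rho):
        with pytest.raises(ValueError):
            nex_prior_params(rho)


class TestExceedance:
    def test_all_draws_above(self):
        assert exceedance(np.full((100, 1), 0.5), 0.2)[0] == 1.0

    def test_boundary_is_strict(self):
        assert exceedance(np.full((100, 1), 0.2), 0.2)[0] == 0.0

    def test_fractional(self):
        draws = np.array([0.1, 0.3, 0.5, 0.15])[:, None]
        assert exceedance(draws, 0.2)[0] == 0.5

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            exceedance(np.empty((0, 2)), 0.2)


class TestBasketData:
    def test_rejects_counts_above_sample_size(self):
        with pytest.raises(ValueError):
            BasketData(y=[5], n=[4])

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            BasketData(y=[1, 2], n=[10])

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            BasketData(y=[-1], n=[10])


class TestIndependentFit:
    def test_all_responders_certain(self, config, fast_mcmc):
        res = fit_independent(BasketData(y=[24], n=[24]), config, fast_mcmc)
        assert res.exceed_prob[0] > 0.999

    def test_matches_quadrature_oracle(self, config):
        # 1-D adaptive-grid integration of likelihood x prior is ground truth
        oracle = indep_exceed(7, 24, 0.2, float(logit(0.2)), 10.0)
        mcmc = MCMCSettings(n_chains=4, n_warmup=2000, n_samples=25000, seed=11)
        res = fit_independent(BasketData(y=[7], n=[24]), config, mcmc)
        assert res.exceed_prob[0] == pytest.approx(oracle, abs=0.005)

    def test_zero_responders_near_zero(self, config, fast_mcmc):
        res = fit_independent(BasketData(y=[0], n=[24]), config, fast_mcmc)
        assert res.exceed_prob[0] < 0.01

    def test_no_mixture_outputs(self, config, fast_mcmc):
        res = fit_independent(BasketData(y=[3], n=[10]), config, fast_mcmc)
        assert res.delta_draws is None and res.mu_draws is None


class TestSeedDeterminism:
    def test_identical_seed_identical_draws(self, config):
        data = BasketData(y=[3, 4], n=[10, 10])
        mcmc = MCMCSettings(n_chains=2, n_warmup=200, n_samples=400, seed=7)
        a = fit_exnex(data, config, mcmc)
        b = fit_exnex(data, config, mcmc)
        np.testing.assert_array_equal(a.theta_draws, b.theta_draws)
        np.testing.assert_array_equal(a.delta_draws, b.delta_draws)

    def test_different_seed_different_draws(self, config):
        data = BasketData(y=[3, 4], n=[10, 10])
        a = fit_exnex(data, config, MCMCSettings(2, 200, 400, seed=7))
        b = fit_exnex(data, config, MCMCSettings(2, 200, 400, seed=8))
        assert not np.array_equal(a.theta_draws, b.theta_draws)


class TestExnexFit:
    #: frozen nested-quadrature values (regenerate with tests/oracle.py:
    #: exnex_exceed at q0=0.2, pi=0.5, rho=0.3, mu0=logit(0.2), nu_mu=10)
    ORACLE_CASES = [
        ((3, 4), (10, 10), (0.774117, 0.917538)),
        ((1, 7), (8, 8), (0.279971, 0.999967)),
    ]

    @pytest.mark.parametrize("y, n, expected", ORACLE_CASES)
    def test_matches_nested_quadrature_oracle(self, config, y, n, expected):
        mcmc = MCMCSettings(n_chains=4, n_warmup=2000, n_samples=12000, seed=3)
        res = fit_exnex(BasketData(y=list(y), n=list(n)), config, mcmc)
        np.testing.assert_allclose(res.exceed_prob, expected, atol=0.01)

    def test_draw_invariants(self, config, fast_mcmc):
        res = fit_exnex(BasketData(y=[3, 4], n=[10, 10]), config, fast_mcmc)
        assert np.all((res.p_draws > 0) & (res.p_draws < 1))
        assert set(np.unique(res.delta_draws)) <= {0.0, 1.0}
        # exceedance equals the strict fraction of draws above q0
        np.testing.assert_allclose(
            res.exceed_prob, (res.p_draws > config.q0).mean(axis=0), atol=1e-12
        )

    def test_nex_degeneracy_reproduces_independent(self):
        """pi = 0 collapses the mixture onto the basket-specific NEX priors."""
        nex = nex_prior_params(0.3)
        mix_cfg = ExnexConfig(pi=0.0, rho=0.3)
        ind_cfg = ExnexConfig(
            indep_prior_mean=float(nex.m[0]), indep_prior_sd=float(np.sqrt(nex.v2[0]))
        )
        data = BasketData(y=[3, 4], n=[10, 10])
        mcmc = MCMCSettings(n_chains=4, n_warmup=1500, n_samples=6000, seed=5)
        mix = fit_exnex(data, mix_cfg, mcmc)
        ind = fit_independent(data, ind_cfg, mcmc)
        np.testing.assert_allclose(mix.exceed_prob, ind.exceed_prob, atol=0.01)

    def test_bhm_degeneracy_all_exchangeable(self, fast_mcmc):
        res = fit_exnex(
            BasketData(y=[3, 4], n=[10, 10]), ExnexConfig(pi=1.0), fast_mcmc
        )
        assert np.all(res.delta_draws == 1.0)

    def test_borrowing_shrinks_posterior_sd(self):
        """Full exchangeability on homogeneous data cannot widen the
        per-basket posterior relative to a stratified analysis."""
        data = BasketData(y=[3, 3, 3, 3], n=[10, 10, 10, 10])
        mcmc = MCMCSettings(n_chains=4, n_warmup=1500, n_samples=6000, seed=9)
        bhm = fit_exnex(data, ExnexConfig(pi=1.0), mcmc)
        ind = fit_independent(data, ExnexConfig(), mcmc)
        assert np.all(bhm.post_sd <= ind.post_sd + 0.005)

    def test_borrowing_lifts_small_homogeneous_basket(self, config):
        """Homogeneous effective data: borrowing pulls the small basket's
        exceedance above its stand-alone value."""
        data = BasketData(y=[10, 10, 10, 10, 6], n=[24, 24, 24, 24, 14])
        mcmc = MCMCSettings(n_chains=2, n_warmup=1000, n_samples=5000, seed=13)
        mix = fit_exnex(data, config, mcmc)
        ind = fit_independent(data, config, mcmc)
        assert mix.exceed_prob[4] > ind.exceed_prob[4]

    def test_exceedance_monotone_in_responders(self, config):
        """With everything else fixed, more responders never lowers the
        posterior exceedance probability (checked over all y in 0..n)."""
        n = np.array([10, 10])
        Y = np.column_stack([np.arange(11), np.full(11, 4)])
        mcmc = MCMCSettings(n_chains=2, n_warmup=1500, n_samples=15000, seed=17)
        bp = fit_exnex_batch(Y, n, config, mcmc)
        steps = np.diff(bp.exceed_prob[:, 0])
        assert np.all(steps > -0.01)

    def test_empty_trial_rejected(self, config, fast_mcmc):
        with pytest.raises(ValueError):
            fit_exnex_batch(np.empty((0, 0)), np.empty(0), config, fast_mcmc)
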