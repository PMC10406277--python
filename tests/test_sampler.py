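import numpy as np
import pytest
from scipy import stats

from blfdr import LinkStatsTable, ModelParams, blfdr_posterior
from blfdr.mixture import HyperParams
from blfdr.sampler import (
    ChainState,
    SamplerConfig,
    _gamma_log_target,
    _Workspace,
    blfdr_from_summary,
    initialize,
    mtm_step,
    run_chains,
    update_alpha_mtm,
    update_beta,
    update_gamma_mtm,
    update_latent,
    update_sigma0_sq,
)

from conftest import simulate_from_model


def make_state(table, alpha=(0.3, 0.1), gamma=(-1.0, 0.2), beta=1.0, sigma0_sq=1.0, w=None):
    if w is None:
        w = np.zeros(table.m, dtype=np.int8)
    w = np.asarray(w, dtype=np.int8)
    return ChainState(alpha=alpha, gamma=gamma, beta=beta, sigma0_sq=sigma0_sq,
                      w=w, p=w.astype(float))


class TestInitialize:
    def test_quantile_threshold_count(self):
        # t_f = 1..100: the 0.94 empirical quantile leaves exactly 6 above it
        t_f = np.arange(1.0, 101.0)
        table = LinkStatsTable(t_f, np.zeros(100))
        state = initialize(table, SamplerConfig(seed=0), HyperParams())
        assert state.w.sum() == 6
        assert state.beta == 0.1
        assert state.sigma0_sq == 1.0
        assert state.alpha == (0.0, 0.0)

    def test_degenerate_all_null_start(self):
        t_f = np.arange(1.0, 101.0)
        table = LinkStatsTable(t_f, np.zeros(100))
        with pytest.warns(UserWarning):
            state = initialize(table, SamplerConfig(pi0_init=1.0, seed=0), HyperParams())
        assert state.w.sum() == 0
        assert state.gamma[1] == 0.0

    def test_support_rule_overrides_quantile(self):
        # every statistic below mu1: no link may start alternative
        t_f = np.linspace(0.01, 0.5, 60)
        table = LinkStatsTable(t_f, np.linspace(0, 2, 60))
        with pytest.warns(UserWarning):
            state = initialize(table, SamplerConfig(seed=0), HyperParams())
        assert state.w.sum() == 0

    def test_logistic_regression_start_tracks_w(self, rng):
        # large t_f concentrated at high t_s (with overlap, so the logistic
        # regression is non-separable) should give a positive slope start
        t_s = rng.uniform(0, 3, 1000)
        t_f = 0.5 + 0.6 * t_s + rng.gamma(2.0, 0.4, 1000)
        table = LinkStatsTable(t_f, t_s)
        state = initialize(table, SamplerConfig(pi0_init=0.8, seed=0), HyperParams())
        assert 0 < state.w.sum() < 1000
        assert state.gamma[1] > 0


class TestConjugateUpdates:
    """Draws from the full conditionals must match grid-normalized posteriors."""

    def test_beta_prior_draw_when_no_alternatives(self, table5, hyper):
        rng = np.random.default_rng(0)
        state = make_state(table5)
        draws = np.array([update_beta(state, table5, hyper, rng) for _ in range(20000)])
        ks = stats.kstest(draws, stats.gamma(a=1.0, scale=1.0).cdf).statistic
        assert ks < 0.02

    def test_beta_grid_posterior(self, table5, hyper):
        w = np.array([0, 1, 1, 1, 0], dtype=np.int8)
        state = make_state(table5, w=w)
        rng = np.random.default_rng(1)
        draws = np.array([update_beta(state, table5, hyper, rng) for _ in range(100000)])
        # independent oracle: normalize prior x Eq-(13) likelihood kernel on a grid
        grid = np.linspace(1e-4, 20, 40001)
        a0, a1 = state.alpha
        shape_i = np.exp(a0 + a1 * table5.t_s[w == 1])
        logp = (hyper.a_beta - 1) * np.log(grid) - hyper.b_beta * grid
        for sh, tf in zip(shape_i, table5.t_f[w == 1]):
            logp += sh * np.log(grid) - grid * (tf - hyper.mu1)
        dens = np.exp(logp - logp.max())
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        ks = stats.kstest(draws, lambda x: np.interp(x, grid, cdf)).statistic
        assert ks < 0.02

    def test_sigma_prior_mean_and_variance(self, hyper):
        # Inverse-Gamma(3, 2) has mean 1 and variance 1
        prior = stats.invgamma(hyper.a_sigma, scale=hyper.b_sigma)
        assert prior.mean() == pytest.approx(1.0)
        assert prior.var() == pytest.approx(1.0)

    def test_sigma_grid_posterior(self, table5, hyper):
        w = np.zeros(5, dtype=np.int8)
        state = make_state(table5, w=w)
        rng = np.random.default_rng(2)
        draws = np.array([update_sigma0_sq(state, table5, hyper, rng) for _ in range(100000)])
        shape = hyper.a_sigma + 2.5
        scale = hyper.b_sigma + 0.5 * (table5.t_f**2).sum()
        ks = stats.kstest(draws, stats.invgamma(shape, scale=scale).cdf).statistic
        assert ks < 0.02

    def test_beta_update_reduces_to_documented_parameters(self, hyper):
        # sum of shapes 5, sum of excesses 3 -> Gamma(6, 4), mean 1.5
        t_f = np.array([0.674 + 1.0, 0.674 + 2.0])
        t_s = np.array([0.0, 0.0])
        table = LinkStatsTable(t_f, t_s)
        state = make_state(table, alpha=(np.log(2.5), 0.0), w=np.array([1, 1]))
        rng = np.random.default_rng(3)
        draws = np.array([update_beta(state, table, hyper, rng) for _ in range(50000)])
        ks = stats.kstest(draws, stats.gamma(a=6.0, scale=0.25).cdf).statistic
        assert ks < 0.02
        assert draws.mean() == pytest.approx(1.5, rel=0.02)


class TestLatentUpdate:
    def test_support_and_complement_of_posterior(self, table5, hyper, table1_params):
        state = make_state(
            table5,
            alpha=table1_params.alpha,
            gamma=table1_params.gamma,
            beta=table1_params.beta,
            sigma0_sq=table1_params.sigma0_sq,
        )
        rng = np.random.default_rng(0)
        w, p = update_latent(state, table5, hyper, rng)
        below = table5.t_f <= hyper.mu1
        assert np.all(p[below] == 0.0)
        assert np.all(w[below] == 0)
        want = 1.0 - blfdr_posterior(table5.t_f, table5.t_s, table1_params, hyper)
        np.testing.assert_allclose(p, want, rtol=1e-10)

    def test_degenerate_prior_gives_zero_probabilities(self, table5, hyper):
        state = make_state(table5, gamma=(-500.0, 0.0))
        rng = np.random.default_rng(0)
        w, p = update_latent(state, table5, hyper, rng)
        assert np.all(p < 1e-100) and np.all(w == 0)


class TestMtm:
    def test_prior_only_target_moments(self, hyper):
        # with no alternative links the alpha conditional is its N2(0, I) prior
        table = LinkStatsTable(np.array([0.1, 0.2, 0.3]), np.array([0.0, 1.0, 2.0]))
        config = SamplerConfig(seed=0)
        state = make_state(table)
        rng = np.random.default_rng(4)
        x = np.zeros(2)
        samples = np.empty((40000, 2))
        for i in range(40000):
            st = make_state(table, alpha=tuple(x))
            x_new, _ = update_alpha_mtm(st, table, hyper, config, rng, scale=1.5)
            x = np.asarray(x_new)
            samples[i] = x
        s = samples[4000:]
        np.testing.assert_allclose(s.mean(axis=0), 0.0, atol=0.06)
        np.testing.assert_allclose(s.var(axis=0), 1.0, atol=0.08)

    def test_gamma_stationary_moments_match_grid(self, table5, hyper):
        """MTM chain moments vs 2-D grid integration of the gamma conditional."""
        w = np.array([0, 1, 0, 1, 0])
        ws = _Workspace(table5, hyper)
        lt = _gamma_log_target(ws, float(w.sum()), float((w * table5.t_s).sum()))
        g0 = np.linspace(-6, 4, 241)
        g1 = np.linspace(-5, 5, 241)
        G0, G1 = np.meshgrid(g0, g1, indexing="ij")
        lp = lt(np.column_stack([G0.ravel(), G1.ravel()])).reshape(G0.shape)
        pgrid = np.exp(lp - lp.max())
        pgrid /= pgrid.sum()
        want_mean = np.array([(pgrid * G0).sum(), (pgrid * G1).sum()])
        want_var = np.array(
            [(pgrid * (G0 - want_mean[0]) ** 2).sum(), (pgrid * (G1 - want_mean[1]) ** 2).sum()]
        )

        rng = np.random.default_rng(5)
        x = np.zeros(2)
        n = 120000
        samples = np.empty((n, 2))
        for i in range(n):
            x, _ = mtm_step(x, lt, 1.2, rng, k=5, nu=hyper.nu)
            samples[i] = x
        s = samples[n // 10:]
        np.testing.assert_allclose(s.mean(axis=0), want_mean, atol=0.05)
        np.testing.assert_allclose(s.var(axis=0), want_var, rtol=0.12)

    def test_single_try_reduces_to_metropolis(self, table5, hyper):
        # k = 1 must target the same stationary distribution as k = 5
        w = np.array([0, 1, 0, 1, 0])
        ws = _Workspace(table5, hyper)
        lt = _gamma_log_target(ws, float(w.sum()), float((w * table5.t_s).sum()))
        means = []
        for k, seed in ((1, 6), (5, 7)):
            rng = np.random.default_rng(seed)
            x = np.zeros(2)
            samples = np.empty((60000, 2))
            for i in range(60000):
                x, _ = mtm_step(x, lt, 1.5, rng, k=k, nu=4)
                samples[i] = x
            means.append(samples[6000:].mean(axis=0))
        np.testing.assert_allclose(means[0], means[1], atol=0.08)

    def test_all_null_w_pushes_gamma0_negative(self, table5, hyper):
        config = SamplerConfig(seed=0)
        state = make_state(table5, gamma=(0.0, 0.0))
        rng = np.random.default_rng(8)
        g = np.zeros(2)
        samples = np.empty((20000, 2))
        for i in range(20000):
            st = make_state(table5, gamma=tuple(g))
            g_new, _ = update_gamma_mtm(st, table5, hyper, config, rng, scale=1.0)
            g = np.asarray(g_new)
            samples[i] = g
        assert samples[2000:, 0].mean() < 0

    def test_nonidentifiable_slope_falls_back_to_prior(self, hyper):
        # constant t_s: only g0 + g1*c identified; prior keeps the slope proper
        t_s = np.full(60, 1.0)
        t_f = np.linspace(0.1, 3.0, 60)
        table = LinkStatsTable(t_f, t_s)
        w = (t_f > 2.5).astype(int)
        ws = _Workspace(table, hyper)
        lt = _gamma_log_target(ws, float(w.sum()), float((w * t_s).sum()))
        rng = np.random.default_rng(9)
        x = np.zeros(2)
        samples = np.empty((60000, 2))
        for i in range(60000):
            x, _ = mtm_step(x, lt, 1.2, rng, k=5, nu=4)
            samples[i] = x
        # marginal variance of the direction orthogonal to identification
        # (g0 - g1)/sqrt(2) is data-informed; (g0 + g1) only via the prior mix
        var_slope = samples[6000:, 1].var()
        assert 0.3 < var_slope < 1.7


class TestRunChains:
    def test_retained_draw_count_default_protocol(self):
        config = SamplerConfig()
        assert config.n_chains * config.n_retained_per_chain == 9000

    def test_determinism_and_summary_shape(self, rng, table1_params):
        table = simulate_from_model(table1_params, 400, rng)
        config = SamplerConfig(n_chains=2, n_iter=400, burn_in=100, thin=5, seed=123)
        s1 = run_chains(table, config)
        s2 = run_chains(table, config)
        np.testing.assert_array_equal(s1.draws, s2.draws)
        assert s1.n_retained == 2 * 60
        assert set(s1.table.index) == {"alpha0", "alpha1", "beta", "gamma0", "gamma1", "sigma0_sq"}
        assert (s1.table["q2.5"] <= s1.table["median"]).all()
        assert (s1.table["median"] <= s1.table["q97.5"]).all()
        assert 0 < s1.acceptance_rates["alpha"] < 1
        assert 0 < s1.acceptance_rates["gamma"] < 1

    def test_blfdr_from_summary_is_plugin_of_medians(self, rng, table1_params):
        table = simulate_from_model(table1_params, 400, rng)
        config = SamplerConfig(n_chains=1, n_iter=300, burn_in=100, thin=4, seed=3)
        summary = run_chains(table, config)
        vals = blfdr_from_summary(table, summary)
        want = blfdr_posterior(table.t_f, table.t_s, summary.median_params())
        np.testing.assert_allclose(vals, want)
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(vals[table.t_f <= 0.674] == 1.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            SamplerConfig(thin=0)
        with pytest.raises(ValueError):
            SamplerConfig(pi0_init=0.0)


class TestSuccessiveConditionalCalibration:
    def test_gibbs_conditionals_preserve_the_prior(self):
        """Geweke-style check: alternating one Gibbs sweep with re-simulation
        of the data given the current parameters is a Markov chain whose
        parameter marginals are exactly the priors -- any error in a full
        conditional shows up as drift.  Run with tightened coefficient priors
        and a small t_s spread so gamma shapes stay in the range where
        double-precision gamma draws do not underflow onto the support
        boundary (tiny shapes put nearly all mass below 1e-300)."""
        from blfdr.mixture import prior_prob_alt as _ppa
        from blfdr.sampler import _alpha_log_target, _gamma_log_target, _Workspace

        rng = np.random.default_rng(123)
        hy = HyperParams(Sigma_alpha=0.25 * np.eye(2), Sigma_gamma=0.25 * np.eye(2))
        m, n_sweeps = 120, 32000
        alpha = np.zeros(2)
        gamma = np.zeros(2)
        beta, s2 = 1.0, 1.0
        out = np.empty((n_sweeps, 6))
        for it in range(n_sweeps):
            t_s = np.abs(rng.normal(0, 0.3, m))
            w = rng.random(m) < _ppa(t_s, gamma)
            t_f = np.abs(rng.normal(0, np.sqrt(s2), m))
            if w.any():
                t_f[w] = hy.mu1 + rng.gamma(np.exp(alpha[0] + alpha[1] * t_s[w]), 1.0 / beta)
            ws = _Workspace(LinkStatsTable(t_f, t_s), hy)
            with np.errstate(divide="ignore"):  # rare exact-underflow draws
                log_d = np.log(t_f[w] - hy.mu1) if w.any() else np.empty(0)
            lt_a = _alpha_log_target(ws, t_s[w], log_d, np.log(beta))
            alpha, _ = mtm_step(alpha, lt_a, 0.6, rng, k=5, nu=hy.nu)
            lt_g = _gamma_log_target(ws, float(w.sum()), float(t_s[w].sum()))
            gamma, _ = mtm_step(gamma, lt_g, 0.6, rng, k=5, nu=hy.nu)
            beta = rng.gamma(
                hy.a_beta + np.exp(alpha[0] + alpha[1] * t_s[w]).sum(),
                1.0 / (hy.b_beta + (t_f[w] - hy.mu1).sum()),
            )
            s2 = 1.0 / rng.gamma(
                hy.a_sigma + 0.5 * (~w).sum(),
                1.0 / (hy.b_sigma + 0.5 * (t_f[~w] ** 2).sum()),
            )
            out[it] = (alpha[0], alpha[1], beta, gamma[0], gamma[1], s2)

        keep = out[4000::4]
        priors = [
            stats.norm(0, 0.5), stats.norm(0, 0.5), stats.gamma(1),
            stats.norm(0, 0.5), stats.norm(0, 0.5), stats.invgamma(3, scale=2),
        ]
        for i, prior in enumerate(priors):
            ks = stats.kstest(keep[:, i], prior.cdf).statistic
            assert ks < 0.06, f"parameter {PARAM_NAMES_GEWEKE[i]} drifted (KS={ks:.3f})"


PARAM_NAMES_GEWEKE = ("alpha0", "alpha1", "beta", "gamma0", "gamma1", "sigma0_sq")
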