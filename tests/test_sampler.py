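"""Tests for the ARMS envelope machinery and the Gibbs sampler."""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist, chisquare

from ncrm.model import (BaseDistribution, DoseGrid, DPPrior, dirichlet_weights,
                        base_cdf, conditional_logdensity_alpha,
                        conditional_logweights_mu_sigma, repair_monotone)
from ncrm.sampler import (SamplerConfig, arms_draw, build_envelope,
                          gibbs_update_mu_sigma, mh_update_alpha,
                          posterior_summary, run_gibbs,
                          sample_piecewise_exponential)

from conftest import make_trial


class TestEnvelope:
    def test_linear_target_reproduced_exactly(self):
        f = lambda x: 2.0 * x - 1.0
        env = build_envelope(f, [0.2, 0.4, 0.6, 0.8], (0.0, 1.0))
        probes = np.linspace(0.01, 0.99, 57)
        assert np.allclose(env.hull(probes), f(probes), atol=1e-12)

    def test_log_concave_domination(self):
        # classical adaptive-rejection property: hull >= log target
        f = lambda x: beta_dist.logpdf(x, 3.0, 2.0)
        env = build_envelope(f, [0.15, 0.35, 0.55, 0.75, 0.9], (0.0, 1.0))
        probes = np.linspace(1e-3, 1 - 1e-3, 100)
        assert np.all(env.hull(probes) >= f(probes) - 1e-10)

    def test_two_abscissae_single_chord(self):
        f = lambda x: -((x - 0.5) ** 2)
        env = build_envelope(f, [0.3, 0.7], (0.0, 1.0))
        chord = lambda x: f(0.3) + (f(0.7) - f(0.3)) / 0.4 * (x - 0.3)
        for x in (0.35, 0.5, 0.65):
            assert env.hull(x) == pytest.approx(chord(x), abs=1e-12)

    def test_invalid_abscissae(self):
        f = lambda x: 0.0
        with pytest.raises(ValueError):
            build_envelope(f, [0.5], (0, 1))
        with pytest.raises(ValueError):
            build_envelope(f, [0.0, 0.5], (0, 1))
        with pytest.raises(ValueError):
            build_envelope(lambda x: np.nan, [0.2, 0.5], (0, 1))


class TestPiecewiseExponential:
    def test_flat_hull_is_uniform(self, rng):
        env = build_envelope(lambda x: 0.0, [0.25, 0.5, 0.75], (0.0, 1.0))
        draws = np.array([sample_piecewise_exponential(env, rng)
                          for _ in range(10000)])
        se = 1 / np.sqrt(12 * 10000)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_truncated_exponential_cdf(self, rng):
        # a linear log target yields a single-chord hull; the fraction of
        # draws below the midpoint must match the closed-form CDF
        s = 3.0
        env = build_envelope(lambda x: s * x, [0.3, 0.7], (0.0, 1.0))
        draws = np.array([sample_piecewise_exponential(env, rng)
                          for _ in range(20000)])
        cdf_mid = (np.exp(s * 0.5) - 1) / (np.exp(s) - 1)
        frac = (draws < 0.5).mean()
        se = np.sqrt(cdf_mid * (1 - cdf_mid) / draws.size)
        assert abs(frac - cdf_mid) < 3 * se

    def test_seed_determinism(self):
        env = build_envelope(lambda x: x, [0.3, 0.7], (0.0, 1.0))
        a = [sample_piecewise_exponential(env, np.random.default_rng(5))
             for _ in range(3)]
        b = [sample_piecewise_exponential(env, np.random.default_rng(5))
             for _ in range(3)]
        assert a == b


class TestArmsDraw:
    def test_beta22_moments(self, rng):
        f = lambda x: beta_dist.logpdf(x, 2.0, 2.0)
        cfg = SamplerConfig(n_burnin=1, n_keep=1)
        x = 0.5
        chain = np.empty(20000)
        for i in range(chain.size):
            x = arms_draw(f, (0.0, 1.0), x, cfg, rng)
            chain[i] = x
        assert chain.mean() == pytest.approx(0.5, abs=0.01)
        assert chain.var() == pytest.approx(0.05, abs=0.005)

    def test_log_concave_never_mh_rejects(self, rng):
        # the hull dominates a log-concave target, so the Metropolis
        # correction must always accept
        f = lambda x: beta_dist.logpdf(x, 3.0, 2.0)
        cfg = SamplerConfig(n_burnin=1, n_keep=1)
        x = 0.5
        for _ in range(2000):
            x, info = arms_draw(f, (0.0, 1.0), x, cfg, rng, return_info=True)
            assert not info["mh_rejected"]

    def test_non_log_concave_target_valid(self, rng):
        # bimodal Beta mixture: ARMS must still hit the right mean
        def f(x):
            return np.logaddexp(beta_dist.logpdf(x, 2, 8),
                                beta_dist.logpdf(x, 8, 2)) - np.log(2)
        cfg = SamplerConfig(n_burnin=1, n_keep=1)
        x = 0.5
        chain = np.empty(20000)
        for i in range(chain.size):
            x = arms_draw(f, (0.0, 1.0), x, cfg, rng)
            chain[i] = x
        assert chain.mean() == pytest.approx(0.5, abs=0.015)


class TestAlphaUpdate:
    def test_always_accept_uphill(self, grid8, base62, rng):
        trial = make_trial([3], [1])
        prior = DPPrior(alpha=5.0, base=base62, a=2.0, b=2.0)
        p = [0.2]
        kern = lambda a: conditional_logdensity_alpha(a, p, base62, trial,
                                                      grid8, 2.0, 2.0)
        # start from an extremely unlikely alpha so every proposal is uphill
        grid_a = np.linspace(1, 20, 100)
        worst = grid_a[np.argmin([kern(a) for a in grid_a])]
        accepted = sum(
            mh_update_alpha(worst, p, prior, trial, grid8, rng) != worst
            for _ in range(50))
        assert accepted >= 48  # near-certain acceptance from the antimode

    def test_stationary_histogram_matches_conditional(self, grid8, base62, rng):
        trial = make_trial([6, 6], [1, 2])
        prior = DPPrior(alpha=5.0, base=base62, a=2.0, b=0.5)
        p = [0.15, 0.4]
        alpha = 5.0
        n_iter, burn = 20000, 500
        chain = np.empty(n_iter)
        for i in range(n_iter):
            alpha = mh_update_alpha(alpha, p, prior, trial, grid8, rng)
            chain[i] = alpha
        chain = chain[burn:]
        edges = np.linspace(1, 20, 21)
        grid_a = np.linspace(1, 20, 4001)
        logk = np.array([conditional_logdensity_alpha(a, p, base62, trial,
                                                      grid8, 2.0, 0.5)
                         for a in grid_a])
        dens = np.exp(logk - logk.max())
        dens /= np.trapezoid(dens, grid_a)
        expected = np.array([np.trapezoid(
            dens[(grid_a >= lo) & (grid_a <= hi)],
            grid_a[(grid_a >= lo) & (grid_a <= hi)])
            for lo, hi in zip(edges[:-1], edges[1:])])
        expected /= expected.sum()
        counts = np.histogram(chain, bins=edges)[0]
        stat, pval = chisquare(counts, expected * counts.sum())
        assert pval > 1e-4

    def test_seed_reproducibility(self, grid8, base62):
        trial = make_trial([3], [1])
        prior = DPPrior(alpha=5.0, base=base62)
        seq1 = [mh_update_alpha(5.0, [0.2], prior, trial, grid8,
                                np.random.default_rng(3)) for _ in range(4)]
        seq2 = [mh_update_alpha(5.0, [0.2], prior, trial, grid8,
                                np.random.default_rng(3)) for _ in range(4)]
        assert seq1 == seq2


class TestMuSigmaUpdate:
    def test_single_point_grid(self, grid8, rng):
        prior = DPPrior(alpha=5.0, base=BaseDistribution(6.0, 2.0), grid_size=1)
        trial = make_trial([3], [1])
        mu, sig = gibbs_update_mu_sigma([0.2], 5.0, prior, trial, grid8, rng)
        assert (mu, sig) == (6.0, 2.0)

    def test_frequencies_match_weights(self, grid8, rng):
        prior = DPPrior(alpha=5.0, base=BaseDistribution(6.0, 2.0), r=2.0,
                        grid_size=3)
        trial = make_trial([6, 3], [1, 1])
        p = [0.15, 0.35]
        mu_g, sig_g, W = conditional_logweights_mu_sigma(p, 5.0, prior, trial,
                                                         grid8)
        n = 4000
        counts = np.zeros_like(W)
        for _ in range(n):
            mu, sig = gibbs_update_mu_sigma(p, 5.0, prior, trial, grid8, rng)
            counts[np.where(mu_g == mu)[0][0], np.where(sig_g == sig)[0][0]] += 1
        freq = counts / n
        se = np.sqrt(W * (1 - W) / n)
        assert np.all(np.abs(freq - W) <= 3 * se + 1e-3)

    def test_joint_and_sequential_agree_in_mean(self, grid8, rng):
        prior = DPPrior(alpha=5.0, base=BaseDistribution(6.0, 2.0), r=1.0,
                        grid_size=3)
        trial = make_trial([6, 3], [1, 1])
        p = [0.15, 0.35]
        joint = [gibbs_update_mu_sigma(p, 5.0, prior, trial, grid8, rng)[0]
                 for _ in range(2000)]
        seq = [gibbs_update_mu_sigma(p, 5.0, prior, trial, grid8, rng,
                                     joint=False)[0] for _ in range(2000)]
        assert np.mean(joint) == pytest.approx(np.mean(seq), abs=0.1)


class TestRunGibbs:
    def test_prior_recovery(self, grid8):
        # no data: posterior means must reproduce F0(d_k) for every dose
        prior = DPPrior(alpha=5.0, base=BaseDistribution(6.0, 2.0))
        trial = make_trial([], [])
        init = repair_monotone(base_cdf(grid8.dose_values, prior.base))
        draws = run_gibbs(trial, grid8, prior, init,
                          SamplerConfig(n_burnin=1000, n_keep=10000, seed=42))
        f0 = base_cdf(grid8.dose_values, prior.base)
        means = draws.p.mean(axis=0)
        # Monte-Carlo standard error by batch means (20 batches of 500),
        # which accounts for the chain's autocorrelation
        bm = draws.p.reshape(20, -1, grid8.K).mean(axis=1)
        se = bm.std(axis=0, ddof=1) / np.sqrt(20)
        assert np.all(np.abs(means - f0) < 3 * se + 1e-3)

    def test_single_dose_beta_oracle(self, grid8):
        # gamma = (1, 1) via alpha=2 and F0(d_1) = 1/2
        prior = DPPrior(alpha=2.0, base=BaseDistribution(1.0, 1.0))
        trial = make_trial([3], [1])
        draws = run_gibbs(trial, grid8, prior, np.array([0.3]),
                          SamplerConfig(n_burnin=500, n_keep=10000, seed=7))
        a, b = 1 + 1, 2 + 1  # Beta(y+g1, n-y+g2)
        mean, var = a / (a + b), a * b / ((a + b) ** 2 * (a + b + 1))
        se_mean = np.sqrt(var / 10000)
        assert draws.p.mean() == pytest.approx(mean, abs=3 * 3 * se_mean)
        assert draws.p.var() == pytest.approx(var, rel=0.1)

    def test_draws_strictly_ordered(self, table2_trial, grid8, fast_sampler):
        prior = DPPrior(alpha=5.0, base=BaseDistribution(6.0, 2.0))
        init = repair_monotone(base_cdf(grid8.dose_values[:6], prior.base))
        draws = run_gibbs(table2_trial, grid8, prior, init,
                          fast_sampler.replace(seed=1))
        padded = np.hstack([np.zeros((draws.n_keep, 1)), draws.p,
                            np.ones((draws.n_keep, 1))])
        assert np.all(np.diff(padded, axis=1) > 0)

    def test_bit_identical_reruns(self, table2_trial, grid8, fast_sampler):
        prior = DPPrior(alpha=5.0, base=BaseDistribution(6.0, 2.0), alpha_fixed=False)
        init = repair_monotone(base_cdf(grid8.dose_values[:6], prior.base))
        d1 = run_gibbs(table2_trial, grid8, prior, init, fast_sampler.replace(seed=9))
        d2 = run_gibbs(table2_trial, grid8, prior, init, fast_sampler.replace(seed=9))
        assert np.array_equal(d1.p, d2.p)
        assert np.array_equal(d1.alpha, d2.alpha)
        assert np.array_equal(d1.mu, d2.mu)

    def test_unknown_hyperparameters_move(self, table2_trial, grid8):
        prior = DPPrior(alpha=5.0, base=BaseDistribution(6.0, 2.0),
                        alpha_fixed=False, a=2.0, b=2.0, r=1.0)
        init = repair_monotone(base_cdf(grid8.dose_values[:6], prior.base))
        draws = run_gibbs(table2_trial, grid8, prior, init,
                          SamplerConfig(n_burnin=200, n_keep=400, seed=3))
        assert np.unique(draws.alpha).size > 10
        assert np.all((draws.alpha >= 1) & (draws.alpha <= 20))
        assert set(np.unique(draws.mu)) <= set(prior.mu_grid)
        assert set(np.unique(draws.sigma)) <= set(prior.sigma_grid)

    def test_invalid_init_raises(self, grid8):
        prior = DPPrior(alpha=5.0, base=BaseDistribution(6.0, 2.0))
        trial = make_trial([3], [1])
        with pytest.raises(ValueError):
            run_gibbs(trial, grid8, prior, np.array([0.5, 0.4]),
                      SamplerConfig())


class TestPosteriorSummary:
    def test_trivial_cases(self, table2_trial, grid8, fast_sampler):
        prior = DPPrior(alpha=5.0, base=BaseDistribution(6.0, 2.0))
        init = repair_monotone(base_cdf(grid8.dose_values[:6], prior.base))
        draws = run_gibbs(table2_trial, grid8, prior, init,
                          fast_sampler.replace(seed=2))
        p_hat, pb = posterior_summary(draws, 1.0 - 1e-12)
        assert np.all(pb == 1.0)  # every draw lies below a target of ~1
        p_hat2, _ = posterior_summary(draws, 0.3)
        assert np.allclose(p_hat, p_hat2)

    def test_single_dose_prob_matches_beta_cdf(self, grid8):
        prior = DPPrior(alpha=2.0, base=BaseDistribution(1.0, 1.0))
        trial = make_trial([3], [1])
        draws = run_gibbs(trial, grid8, prior, np.array([0.3]),
                          SamplerConfig(n_burnin=500, n_keep=10000, seed=11))
        _, pb = posterior_summary(draws, 0.3)
        target = beta_dist.cdf(0.3, 2, 3)
        se = np.sqrt(target * (1 - target) / 10000)
        assert abs(pb[0] - target) < 3 * 3 * se
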