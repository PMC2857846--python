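"""Mixture-prior Gibbs sampler: full-conditional oracles and chain behaviour."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from growsel import BayesCPi, GsData, McmcConfig, compute_gebv, run_sampler
from growsel.mcmc import (
    inclusion_probability,
    sample_indicator_and_effect,
    sample_pi,
    sample_variances,
)


def _simulate_from_model(rng, n=500, p=100, pi=0.10, h2=0.5):
    """Data drawn from the sampler's own generative model (codes 1/2/3)."""
    freq = rng.uniform(0.1, 0.9, size=p)
    G = rng.binomial(2, freq, size=(n, p)) + 1.0
    k = max(1, int(round(pi * p)))
    idx = rng.choice(p, size=k, replace=False)
    Gc = G - G.mean(axis=0)
    alpha = np.zeros(p)
    alpha[idx] = rng.normal(0.0, 1.0, size=k)
    g = Gc @ alpha
    vg = g.var()
    alpha *= math.sqrt(1.0 / vg)  # genetic variance 1
    g = Gc @ alpha
    ve = (1.0 - h2) / h2
    y = 5.0 + g + rng.normal(0.0, math.sqrt(ve), size=n)
    return G, y, g


class TestInclusionProbability:
    def test_matches_quadrature_oracle(self):
        """Collapsed P(delta=1|rest) equals 1-D integration over the effect."""
        g = np.array([-1.0, -1.0, 1.0, 1.0])
        r = np.array([-1.0, -1.0, 1.0, 1.0])
        s2a, s2e, pi = 1.0, 1.0, 0.5

        def lik(a):
            return np.exp(-0.5 * np.sum((r - a * g) ** 2) / s2e)

        m1, _ = integrate.quad(
            lambda a: lik(a) * stats.norm.pdf(a, 0.0, math.sqrt(s2a)), -30, 30
        )
        m0 = lik(0.0)
        expected = pi * m1 / (pi * m1 + (1 - pi) * m0)
        got = inclusion_probability(g, r, s2a, s2e, pi)
        assert got == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("pi", [0.1, 0.5, 0.9])
    def test_quadrature_oracle_random_instances(self, pi, rng):
        g = rng.normal(size=8)
        g -= g.mean()
        r = rng.normal(size=8)
        s2a, s2e = 0.7, 1.3

        def lik(a):
            return np.exp(-0.5 * np.sum((r - a * g) ** 2) / s2e)

        m1, _ = integrate.quad(
            lambda a: lik(a) * stats.norm.pdf(a, 0.0, math.sqrt(s2a)), -30, 30
        )
        expected = pi * m1 / (pi * m1 + (1 - pi) * lik(0.0))
        assert inclusion_probability(g, r, s2a, s2e, pi) == pytest.approx(expected, abs=1e-6)

    def test_slab_collapse_limit_returns_prior(self):
        g = np.array([-1.0, 0.0, 1.0])
        r = np.array([0.3, -0.1, 0.5])
        assert inclusion_probability(g, r, 1e-300, 1.0, 0.3) == pytest.approx(0.3, abs=1e-9)

    def test_orthogonal_residual_disfavours_inclusion(self):
        g = np.array([-1.0, 1.0, -1.0, 1.0])
        r = np.array([1.0, 1.0, -1.0, -1.0])  # g'r = 0
        assert float(g @ r) == 0.0
        for s2a in (0.1, 1.0, 10.0):
            assert inclusion_probability(g, r, s2a, 1.0, 0.5) < 0.5

    def test_effect_draw_from_normal_full_conditional(self, rng):
        g = np.array([-1.0, -1.0, 1.0, 1.0])
        r = 2.0 * g  # strong signal
        draws = [
            sample_indicator_and_effect(rng, g, r, 4.0, 0.1, 0.9)[1] for _ in range(4000)
        ]
        draws = np.asarray(draws)
        v = float(g @ g) + 0.1 / 4.0
        mean = float(g @ r) / v
        included = draws[draws != 0.0]
        assert included.size > 3900  # overwhelming inclusion evidence
        assert included.mean() == pytest.approx(mean, abs=4 * math.sqrt(0.1 / v / included.size))


class TestSamplePi:
    def test_beta_moments_no_active_snps(self, rng):
        draws = np.array([sample_pi(rng, np.zeros(100)) for _ in range(20000)])
        # Beta(1, 101): mean 1/102
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert draws.mean() == pytest.approx(1 / 102, abs=3 * se)

    def test_symmetry_all_active(self, rng):
        lo = np.array([sample_pi(rng, np.zeros(50)) for _ in range(20000)])
        hi = np.array([sample_pi(rng, np.ones(50)) for _ in range(20000)])
        assert lo.mean() + hi.mean() == pytest.approx(1.0, abs=0.005)

    def test_closed_form_mean_k5_p100(self, rng):
        draws = np.array(
            [sample_pi(rng, np.r_[np.ones(5), np.zeros(95)]) for _ in range(100000)]
        )
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        # Beta(1+5, 1+95) mean = 6/102
        assert draws.mean() == pytest.approx(6 / 102, abs=3 * se)


class TestSampleVariances:
    def test_residual_variance_consistency(self, rng):
        e = rng.normal(0.0, 2.0, size=20000)  # e'e/n ~ 4
        draws = np.array(
            [
                sample_variances(rng, np.zeros(3), np.ones(3), e, anchor_sigma2a=1.0)[1]
                for _ in range(300)
            ]
        )
        assert draws.mean() == pytest.approx(float(e @ e) / e.size, rel=0.02)

    def test_no_active_snps_fallback_positive_and_flagged(self, rng):
        s2a, s2e, fb = sample_variances(
            rng, np.zeros(10), np.zeros(10), rng.normal(size=50), anchor_sigma2a=0.5
        )
        assert fb and np.isfinite(s2a) and s2a > 0

    def test_effect_variance_closed_form_mean(self, rng):
        """10 effects with sum of squares 10: conditional is 10/chi2(8)."""
        alpha = np.full(10, 1.0)
        resid = rng.normal(size=1000)
        draws = np.array(
            [
                sample_variances(rng, alpha, np.ones(10), resid, anchor_sigma2a=1.0)[0]
                for _ in range(100000)
            ]
        )
        # inv-chi2 mean S/(nu-2) = 10/6, sd of mean from the sample itself
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert draws.mean() == pytest.approx(10.0 / 6.0, abs=3 * se)


class TestComputeGebv:
    def test_zero_effects_zero_gebv(self):
        G = np.ones((4, 3))
        np.testing.assert_array_equal(compute_gebv(G, np.zeros(3)), np.zeros(4))

    def test_single_snp_arithmetic(self):
        G = np.array([[1.0], [2.0], [3.0]])
        np.testing.assert_allclose(compute_gebv(G, [2.0]), [-2.0, 0.0, 2.0])

    def test_matches_double_loop_oracle(self, rng):
        G = rng.integers(1, 4, size=(5, 4)).astype(float)
        alpha = rng.normal(size=4)
        means = G.mean(axis=0)
        expected = np.array(
            [sum((G[j, i] - means[i]) * alpha[i] for i in range(4)) for j in range(5)]
        )
        expected -= expected.mean()
        np.testing.assert_allclose(compute_gebv(G, alpha), expected, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            compute_gebv(np.ones((3, 2)), np.ones(3))


class TestRunSampler:
    def test_no_snps_reduces_to_conjugate_normal_mean(self, rng):
        y = rng.normal(3.0, 1.0, size=200)
        data = GsData(y=y, G=np.empty((200, 0)))
        s = run_sampler(data, McmcConfig(burn_in=200, n_samples=400, thin=1, seed=1), keep_trace=True)
        mc_se = s.trace["b0"].std(ddof=1) / math.sqrt(s.n_kept)
        post_sd = math.sqrt(s.sigma2e_mean / y.size)
        assert s.b_mean[0] == pytest.approx(y.mean(), abs=3 * max(mc_se, post_sd))

    def test_non_finite_phenotypes_rejected(self):
        with pytest.raises(ValueError):
            GsData(y=np.array([1.0, np.nan]), G=np.ones((2, 1)))

    def test_null_data_self_consistency(self, rng):
        """Pure-noise phenotypes: inclusion stays rare and tracks pi."""
        G = rng.binomial(2, rng.uniform(0.1, 0.9, 100), size=(300, 100)) + 1.0
        y = rng.normal(size=300)
        s = run_sampler(
            GsData(y=y, G=G), McmcConfig(burn_in=500, n_samples=500, thin=2, seed=2),
            keep_trace=True,
        )
        assert s.pi_mean < 0.5
        pi_se = s.trace["pi"].std(ddof=1) / math.sqrt(s.n_kept)
        # mean posterior inclusion equals mean k/p; relate to pi via Beta mean
        mean_k = s.incl_prob.mean() * 100
        expected_pi = (1 + mean_k) / (2 + 100)
        assert s.pi_mean == pytest.approx(expected_pi, abs=5 * pi_se + 0.01)

    def test_parameter_recovery_from_own_model(self, rng):
        G, y, g = _simulate_from_model(rng)
        s = run_sampler(
            GsData(y=y, G=G), McmcConfig(burn_in=800, n_samples=300, thin=2, seed=3)
        )
        assert 0.03 <= s.pi_mean <= 0.30
        gebv = compute_gebv(G, s.alpha_mean)
        assert stats.pearsonr(g, gebv)[0] >= 0.6

    def test_seed_determinism_bit_identical(self, rng):
        G, y, _ = _simulate_from_model(rng, n=120, p=30)
        cfg = McmcConfig(burn_in=100, n_samples=50, thin=2, seed=11)
        s1 = run_sampler(GsData(y=y, G=G), cfg)
        s2 = run_sampler(GsData(y=y, G=G), cfg)
        np.testing.assert_array_equal(s1.alpha_mean, s2.alpha_mean)
        np.testing.assert_array_equal(s1.incl_prob, s2.incl_prob)
        np.testing.assert_array_equal(s1.gebv, s2.gebv)
        assert s1.pi_mean == s2.pi_mean

    def test_blup_limit_matches_mixed_model_equations(self, rng):
        """delta forced on, variances fixed: posterior mean equals ridge/MME."""
        n, p = 20, 10
        G = rng.integers(1, 4, size=(n, p)).astype(float)
        y = rng.normal(size=n) + G[:, 0]
        s2a, s2e = 0.5, 1.0
        data = GsData(y=y, G=G)
        s = run_sampler(
            data,
            McmcConfig(burn_in=2000, n_samples=4000, thin=5, seed=4),
            update_indicators=False,
            update_pi=False,
            update_variances=False,
            init={"delta": np.ones(p), "sigma2a": s2a, "sigma2e": s2e},
            keep_trace=True,
        )
        # closed-form MME: [X'X  X'Z; Z'X  Z'Z + lambda I] [b; a] = [X'y; Z'y]
        X = np.ones((n, 1))
        Z = G - G.mean(axis=0)
        lam = s2e / s2a
        top = np.hstack([X.T @ X, X.T @ Z])
        bot = np.hstack([Z.T @ X, Z.T @ Z + lam * np.eye(p)])
        sol = np.linalg.solve(np.vstack([top, bot]), np.r_[X.T @ y, Z.T @ y])
        b_exact, a_exact = sol[0], sol[1:]
        # Monte-Carlo SE from posterior spread of kept draws
        mcse_b = s.trace["b0"].std(ddof=1) / math.sqrt(s.n_kept)
        assert s.b_mean[0] == pytest.approx(b_exact, abs=4 * max(mcse_b, 1e-3))
        post_sd = math.sqrt(s2e / (np.einsum("ij,ij->j", Z, Z) + lam).min())
        tol = 4 * post_sd / math.sqrt(s.n_kept) + 0.01
        np.testing.assert_allclose(s.alpha_mean, a_exact, atol=tol)

    def test_pi_recovery_interval_covers_truth(self):
        """Across replicate model-true datasets the pi posterior means bracket 0.1."""
        pis = []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            G, y, _ = _simulate_from_model(rng, n=400, p=100, pi=0.10)
            s = run_sampler(
                GsData(y=y, G=G),
                McmcConfig(burn_in=500, n_samples=200, thin=2, seed=200 + rep),
            )
            pis.append(s.pi_mean)
        lo, hi = np.quantile(pis, [0.05, 0.95])
        assert lo <= 0.10 <= hi

    def test_snp_order_exchangeability_of_posterior_means(self, rng):
        G, y, _ = _simulate_from_model(rng, n=300, p=40, pi=0.2, h2=0.8)
        perm = np.random.default_rng(5).permutation(40)
        cfg = McmcConfig(burn_in=1500, n_samples=800, thin=3, seed=6)
        s1 = run_sampler(GsData(y=y, G=G), cfg)
        s2 = run_sampler(GsData(y=y, G=G[:, perm]), cfg)
        # per-SNP streams are positional, so equality holds only in expectation
        np.testing.assert_allclose(s1.alpha_mean[perm], s2.alpha_mean, atol=0.08)
        np.testing.assert_allclose(s1.incl_prob[perm], s2.incl_prob, atol=0.15)

    def test_duplicated_snp_splits_effect(self, rng):
        """Two identical columns share (not double) the single column's effect."""
        n = 400
        g = rng.binomial(2, 0.5, size=n).astype(float)
        y = 1.5 * (g - g.mean()) + rng.normal(0.0, 0.5, size=n)
        noise = rng.binomial(2, rng.uniform(0.1, 0.9, 10), size=(n, 10)).astype(float)
        cfg = McmcConfig(burn_in=1000, n_samples=600, thin=2, seed=7)
        s_single = run_sampler(GsData(y=y, G=np.column_stack([g, noise])), cfg)
        s_dup = run_sampler(GsData(y=y, G=np.column_stack([g, g, noise])), cfg)
        single_eff = abs(s_single.alpha_mean[0])
        pair_sum = abs(s_dup.alpha_mean[0]) + abs(s_dup.alpha_mean[1])
        assert pair_sum == pytest.approx(single_eff, rel=0.15)

    def test_monomorphic_snps_forced_out(self, rng):
        G = np.column_stack([np.full(50, 2.0), rng.binomial(2, 0.5, 50) + 1.0])
        y = rng.normal(size=50)
        s = run_sampler(GsData(y=y, G=G), McmcConfig(burn_in=50, n_samples=50, thin=1, seed=8))
        assert list(s.monomorphic) == [0]
        assert s.incl_prob[0] == 0.0 and s.alpha_mean[0] == 0.0

    def test_gebv_mean_zero(self, rng):
        G, y, _ = _simulate_from_model(rng, n=150, p=25)
        s = run_sampler(GsData(y=y, G=G), McmcConfig(burn_in=100, n_samples=100, thin=1, seed=9))
        assert abs(s.gebv.mean()) < 1e-8
        assert np.all((s.incl_prob >= 0) & (s.incl_prob <= 1))
        assert 0.0 < s.pi_mean < 1.0


class TestBayesCPiEstimator:
    def test_fit_predict_and_attributes(self, rng):
        G, y, g = _simulate_from_model(rng, n=300, p=50, h2=0.8)
        est = BayesCPi(burn_in=500, n_samples=200, thin=2, random_state=0).fit(G, y)
        assert est.alpha_mean_.shape == (50,)
        assert 0.0 < est.pi_ < 1.0
        pred = est.predict(G)
        assert stats.pearsonr(pred, y)[0] > 0.5
        assert abs(est.genomic_values(G).mean()) < 1e-8

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = BayesCPi(burn_in=10, n_samples=5, thin=1, random_state=3)
        cl = clone(est)
        assert cl.get_params() == est.get_params()
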