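import numpy as np
import pytest
from scipy.stats import binom, norm

import clinescan as cs
from clinescan.model import CLAMP_EPS, sample_null_posterior
from clinescan.types import BetaPrior


class TestStandardize:
    def test_three_point_row(self):
        env = cs.EnvironmentMatrix(["x"], np.array([[1.0, 2.0, 3.0]]))
        out = cs.standardize_environment(env)
        np.testing.assert_allclose(
            out.values[0], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )
        assert out.standardized

    def test_idempotent(self):
        env = cs.EnvironmentMatrix(["x"], np.array([[0.4, -1.3, 2.2, 0.1]]))
        once = cs.standardize_environment(env)
        twice = cs.standardize_environment(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_constant_row_is_an_error_naming_the_variable(self):
        env = cs.EnvironmentMatrix(["flat"], np.array([[5.0, 5.0, 5.0]]))
        with pytest.raises(ValueError, match="flat"):
            cs.standardize_environment(env)


class TestLoglikSnp:
    def test_null_beta_ignores_environment(self):
        om = cs.CovarianceMatrix(np.array([[0.2, 0.05], [0.05, 0.3]]))
        args = dict(count1_row=[3, 7], ntotal_row=[10, 10], theta=[0.3, 0.6], alpha=0.4, omega=om)
        a = cs.loglik_snp(**args, beta=0.0, Y_row=[5.0, -2.0])
        b = cs.loglik_snp(**args, beta=0.0, Y_row=[0.0, 0.0])
        assert a == b

    def test_one_population_matches_independent_dense_evaluation(self):
        # P=1: the MVN factor is a plain normal; compare against separately
        # composed normal + binomial terms
        alpha, theta, c, n = 0.35, 0.35, 4, 12
        om = cs.CovarianceMatrix(np.array([[1.0]]))
        got = cs.loglik_snp([c], [n], [theta], alpha, om)
        s = alpha * (1 - alpha)
        expected = norm.logpdf(theta, loc=alpha, scale=np.sqrt(s)) + binom.logpmf(
            c, n, theta
        )
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_clamp_contract_far_outside_unit_interval(self):
        om = cs.CovarianceMatrix(np.array([[1.0]]))  # alpha=0.5 -> normal sd 0.5
        lo = cs.loglik_snp([2], [10], [-3.0], 0.5, om)
        at_eps = cs.loglik_snp([2], [10], [CLAMP_EPS], 0.5, om)
        # binomial factors must agree; only the MVN part differs
        bin_lo = lo - norm.logpdf(-3.0, loc=0.5, scale=0.5)
        bin_eps = at_eps - norm.logpdf(CLAMP_EPS, loc=0.5, scale=0.5)
        np.testing.assert_allclose(bin_lo, bin_eps, rtol=1e-10)

    def test_alpha_out_of_range_fails(self):
        om = cs.CovarianceMatrix(np.array([[0.5]]))
        with pytest.raises(ValueError, match="alpha"):
            cs.loglik_snp([1], [2], [0.5], 1.5, om)


class TestCovarianceEstimation:
    def test_one_population_gives_positive_scalar(self):
        env = cs.EnvironmentMatrix(["x"], np.array([[1.0]]), standardized=False)
        rng = np.random.default_rng(0)
        counts = cs.AlleleCountMatrix(
            snp_ids=[f"s{i}" for i in range(60)],
            chrom=np.array(["chr1"] * 60, dtype=object),
            pos=np.arange(60),
            count1=rng.integers(1, 20, size=(60, 1)),
            ntotal=np.full((60, 1), 20),
        )
        cov, draws = cs.estimate_null_covariance(
            counts, iterations=600, output_interval=150, seed=1
        )
        assert cov.omega.shape == (1, 1)
        assert cov.omega[0, 0] > 0

    def test_same_seed_is_bitwise_identical(self, small_dataset):
        counts = small_dataset[0]
        a, _ = cs.estimate_null_covariance(counts, iterations=600, output_interval=150, seed=9)
        b, _ = cs.estimate_null_covariance(counts, iterations=600, output_interval=150, seed=9)
        assert np.array_equal(a.omega, b.omega)

    def test_too_few_iterations_fail(self, small_dataset):
        counts = small_dataset[0]
        with pytest.raises(ValueError, match="output_interval"):
            cs.estimate_null_covariance(counts, iterations=100, output_interval=50)

    def test_all_fixed_alleles_fail(self):
        counts = cs.AlleleCountMatrix(
            snp_ids=["a", "b"],
            chrom=np.array(["chr1", "chr1"], dtype=object),
            pos=np.array([0, 1000]),
            count1=np.array([[0, 0], [10, 10]]),
            ntotal=np.array([[10, 10], [10, 10]]),
        )
        with pytest.raises(ValueError, match="fixed"):
            cs.estimate_null_covariance(counts, iterations=300, output_interval=100)

    def test_retained_draw_count_matches_schedule(self, small_dataset):
        counts, env, omega = small_dataset[:3]
        draws = sample_null_posterior(counts, omega, iterations=1000, seed=2, thin=50)
        # burn-in is half the chain; one draw per thin interval afterwards
        assert draws.n_draws == (1000 - 500) // 50
        assert draws.n_snps == counts.n_snps


class TestBayesFactor:
    def test_point_mass_prior_gives_bf_of_one(self, small_dataset):
        counts, env, omega = small_dataset[:3]
        draws = sample_null_posterior(counts, omega, iterations=400, seed=3, thin=20)
        bf = cs.bayes_factor(0, env.values[0], draws, prior=BetaPrior("point-mass", 0.0))
        assert bf == 1.0

    def test_zero_environment_gives_bf_of_one(self, small_dataset):
        counts, env, omega = small_dataset[:3]
        draws = sample_null_posterior(counts, omega, iterations=400, seed=3, thin=20)
        bf = cs.bayes_factor(0, np.zeros(counts.n_pops), draws)
        assert bf == pytest.approx(1.0, abs=1e-12)

    def test_empty_draws_fail(self, small_dataset):
        counts, env, omega = small_dataset[:3]
        draws = sample_null_posterior(counts, omega, iterations=400, seed=3, thin=20)
        empty = cs.NullPosteriorDraws(
            omega=draws.omega[:0], alpha=draws.alpha[:0], theta=draws.theta[:0],
            iteration=draws.iteration[:0],
        )
        with pytest.raises(ValueError, match="empty"):
            cs.bayes_factor(0, env.values[0], empty)


class TestRunScan:
    def test_shape_and_determinism(self, small_dataset):
        counts, env, omega = small_dataset[:3]
        a = cs.run_scan(counts, env, omega=omega, iterations=600, seed=4, thin=25)
        b = cs.run_scan(counts, env, omega=omega, iterations=600, seed=4, thin=25)
        assert a.log10_bf.shape == (counts.n_snps, env.n_vars)
        assert np.all(np.isfinite(a.log10_bf))
        assert np.array_equal(a.log10_bf, b.log10_bf)
        assert a.seed == 4 and a.iterations == 600

    def test_dimension_mismatch_fails(self, small_dataset):
        counts, env, omega = small_dataset[:3]
        bad_env = cs.make_environment(counts.n_pops + 1, seed=0)
        with pytest.raises(ValueError, match="populations"):
            cs.run_scan(counts, bad_env, omega=omega, iterations=600, seed=4)

    def test_unstandardized_environment_fails(self, small_dataset):
        counts, env, omega = small_dataset[:3]
        raw = cs.EnvironmentMatrix(env.var_names, env.values * 3 + 1)
        with pytest.raises(ValueError, match="standardized"):
            cs.run_scan(counts, raw, omega=omega, iterations=600, seed=4)

    def test_bf_invariant_to_environment_shift_before_standardization(self, small_dataset):
        counts, env, omega = small_dataset[:3]
        raw = cs.EnvironmentMatrix(env.var_names, env.values.copy())
        shifted = cs.EnvironmentMatrix(env.var_names, env.values + 17.0)
        a = cs.run_scan(counts, cs.standardize_environment(raw), omega=omega, iterations=600, seed=4, thin=25)
        b = cs.run_scan(counts, cs.standardize_environment(shifted), omega=omega, iterations=600, seed=4, thin=25)
        np.testing.assert_allclose(a.log10_bf, b.log10_bf, atol=1e-10)

    def test_power_ordering_median_bf_nondecreasing_in_effect_size(self):
        # median BF over SNPs must rise with |beta*|
        env = cs.make_environment(8, seed=3)
        omega = cs.make_covariance(8, seed=2)
        medians = []
        for beta in (0.0, 0.3, 0.6):
            effects = {"gradient": (40, beta)} if beta else None
            counts, _, truth = cs.simulate_dataset(
                P=8, L=40, n_chrom=50, omega=omega, env=env, effects=effects, seed=21
            )
            scan = cs.run_scan(counts, env, omega=omega, iterations=1500, seed=8, thin=25)
            medians.append(np.median(scan.log10_bf[:, 0]))
        assert medians[0] <= medians[1] <= medians[2]
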