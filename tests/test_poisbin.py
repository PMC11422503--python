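"""Poisson-binomial machinery and threshold adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import beta as beta_dist, binom

from conftest import brute_force_poisbin_pmf
from pancore.poisbin import (
    ThresholdConfig,
    adjust_core_threshold,
    adjust_rare_threshold,
    poisbin_cdf,
    poisbin_pmf_exact,
    sample_conditional_theta,
    simulate_observation_counts,
    unadjusted_cutoffs,
)


class TestPmf:
    def test_all_certain_successes(self):
        assert poisbin_pmf_exact([1.0, 1.0, 1.0]).tolist() == [0, 0, 0, 1]

    def test_single_bernoulli(self):
        assert poisbin_pmf_exact([0.5]).tolist() == [0.5, 0.5]

    def test_enumeration_example(self):
        # P(X=0) = 0.1*0.2*0.3, P(X=1) by the three single-success paths
        pmf = poisbin_pmf_exact([0.9, 0.8, 0.7])
        assert pmf[0] == pytest.approx(0.006)
        assert pmf[1] == pytest.approx(0.092)
        assert pmf[:2].sum() == pytest.approx(0.098)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), n=st.integers(1, 10))
    def test_matches_brute_force_enumeration(self, seed, n):
        probs = np.random.default_rng(seed).random(n)
        np.testing.assert_allclose(
            poisbin_pmf_exact(probs), brute_force_poisbin_pmf(probs), atol=1e-10
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 1.0), n=st.integers(1, 50))
    def test_equal_probability_is_binomial(self, p, n):
        np.testing.assert_allclose(
            poisbin_pmf_exact([p] * n), binom.pmf(np.arange(n + 1), n, p), atol=1e-10
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**20), n=st.integers(1, 200))
    def test_sums_to_one(self, seed, n):
        probs = np.random.default_rng(seed).random(n)
        assert poisbin_pmf_exact(probs).sum() == pytest.approx(1.0, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            poisbin_pmf_exact([0.5, 1.2])


class TestCdf:
    def test_all_success_lower_tail(self):
        assert poisbin_cdf([1.0] * 5, 4) == 0.0

    def test_full_support(self):
        assert poisbin_cdf([0.3, 0.8, 0.1], 3) == pytest.approx(1.0)

    def test_binomial_closed_form(self):
        assert poisbin_cdf([0.95] * 3, 1) == pytest.approx(0.00725)
        assert poisbin_cdf([0.95] * 3, 1) == pytest.approx(binom.cdf(1, 3, 0.95))

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="k must be"):
            poisbin_cdf([0.5], 2)


class TestConditionalTheta:
    def test_uniform_prior_core_region(self):
        cfg = ThresholdConfig(prior_a=1.0, prior_b=1.0)
        draws = sample_conditional_theta(cfg, "core", 100_000, rng=1)
        assert draws.min() >= 0.95
        # truncated uniform on [0.95, 1]: mean 0.975, sd 0.05/sqrt(12)
        se = 0.05 / np.sqrt(12) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.975) < 3 * se

    def test_u_prior_support_contract(self):
        cfg = ThresholdConfig(prior_a=0.5, prior_b=0.5)
        draws = sample_conditional_theta(cfg, "core", 100_000, rng=2)
        assert np.all(draws >= 0.95) and np.all(draws <= 1.0)

    def test_rare_region_mean_matches_numeric_integration(self):
        a = b = 0.5
        cfg = ThresholdConfig(prior_a=a, prior_b=b)
        draws = sample_conditional_theta(cfg, "rare", 100_000, rng=3)
        mass = beta_dist.cdf(0.05, a, b)
        mean_exact = (
            integrate.quad(lambda x: x * beta_dist.pdf(x, a, b), 0, 0.05)[0] / mass
        )
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - mean_exact) < 3 * se

    def test_negligible_region_mass_errors(self):
        cfg = ThresholdConfig(prior_a=1.0, prior_b=5000.0)
        with pytest.raises(ValueError, match="prior"):
            sample_conditional_theta(cfg, "core", 10)


class TestSimulateCounts:
    def test_deterministic_all_success(self):
        counts = simulate_observation_counts([1.0] * 7, [1.0] * 20, rng=0)
        assert np.all(counts == 7)

    def test_thinning_mean(self):
        n, draws = 1000, 400
        counts = simulate_observation_counts([0.5] * n, [1.0] * draws, rng=4)
        se = np.sqrt(0.25 / n) / np.sqrt(draws)
        assert abs(counts.mean() / n - 0.5) < 3 * se

    def test_empirical_cdf_within_dkw_band(self):
        rng = np.random.default_rng(5)
        completeness = rng.uniform(0.6, 1.0, size=40)
        theta = 0.9
        n_draws = 4000
        counts = simulate_observation_counts(
            completeness, [theta] * n_draws, rng=6
        )
        exact = np.cumsum(poisbin_pmf_exact(theta * completeness))
        empirical = np.searchsorted(np.sort(counts), np.arange(41), side="right") / n_draws
        eps = np.sqrt(np.log(2 / 1e-6) / (2 * n_draws))
        assert np.max(np.abs(empirical - exact)) < eps


class TestCoreThreshold:
    def test_binomial_alpha_quantile_closed_form(self):
        # complete genomes, prior a point mass at t_core: Binomial(3, 0.95)
        # has P(X<=1)=0.00725 <= 0.05 < P(X<=2)=0.142625
        for method in ("exact", "montecarlo"):
            cfg = ThresholdConfig(fixed_theta=0.95, method=method, seed=11)
            x, fnr = adjust_core_threshold([1.0] * 3, cfg)
            assert x == 1
            assert fnr <= 0.05
        cfg = ThresholdConfig(fixed_theta=0.95, method="exact")
        _, fnr = adjust_core_threshold([1.0] * 3, cfg)
        assert fnr == pytest.approx(0.00725)

    def test_degenerate_prior_at_one(self):
        cfg = ThresholdConfig(fixed_theta=1.0, method="exact")
        x, fnr = adjust_core_threshold([1.0] * 8, cfg)
        assert (x, fnr) == (7, 0.0)

    def test_sentinel_when_no_cutoff_satisfies_bound(self):
        # single nearly-empty genome: even X*=0 exceeds a tight bound
        cfg = ThresholdConfig(fixed_theta=0.95, alpha=0.01, method="exact")
        x, fnr = adjust_core_threshold([0.5], cfg)
        assert x == -1 and fnr == 0.0

    def test_empty_completeness_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            adjust_core_threshold([], ThresholdConfig())

    def test_montecarlo_matches_exact_small_n(self):
        rng = np.random.default_rng(12)
        agree = 0
        n_cfg = 20
        for k in range(n_cfg):
            completeness = rng.uniform(0.5, 1.0, size=int(rng.integers(3, 11)))
            cfg = ThresholdConfig(
                prior_a=float(rng.uniform(0.3, 2.0)),
                prior_b=float(rng.uniform(0.3, 2.0)),
                n_sims=200_000,
                seed=int(rng.integers(2**31)),
            )
            x_mc, _ = adjust_core_threshold(completeness, cfg)
            x_exact, _ = adjust_core_threshold(completeness, cfg.with_(method="exact"))
            agree += x_mc == x_exact
        assert agree >= int(0.95 * n_cfg)

    def test_monotone_in_completeness(self):
        # lowering completeness elementwise can only lower the core cutoff
        rng = np.random.default_rng(13)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            high = rng.uniform(0.6, 1.0, size=n)
            low = high * rng.uniform(0.5, 1.0, size=n)
            cfg = ThresholdConfig(method="exact")
            x_high, _ = adjust_core_threshold(high, cfg)
            x_low, _ = adjust_core_threshold(low, cfg)
            assert x_low <= x_high

    def test_determinism_per_seed(self):
        completeness = np.random.default_rng(14).uniform(0.7, 1.0, size=50)
        cfg = ThresholdConfig(seed=99, n_sims=20_000)
        assert adjust_core_threshold(completeness, cfg) == adjust_core_threshold(
            completeness, cfg
        )
        assert adjust_rare_threshold(completeness, cfg) == adjust_rare_threshold(
            completeness, cfg
        )


class TestRareThreshold:
    def test_degenerate_prior_at_zero(self):
        cfg = ThresholdConfig(fixed_theta=0.0, method="exact")
        x, fpr = adjust_rare_threshold([1.0] * 6, cfg)
        assert (x, fpr) == (1, 0.0)

    def test_binomial_closed_form(self):
        # Binomial(3, 0.05): P(X>=1)=0.142625 > 0.05 >= P(X>=2)=0.00725
        for method in ("exact", "montecarlo"):
            cfg = ThresholdConfig(fixed_theta=0.05, method=method, seed=15)
            x, fpr = adjust_rare_threshold([1.0] * 3, cfg)
            assert x == 2
            assert fpr <= 0.05

    def test_monotone_in_completeness(self):
        # lower completeness -> fewer spurious observations of rare genes,
        # so the rare cutoff never increases
        rng = np.random.default_rng(16)
        for _ in range(30):
            n = int(rng.integers(3, 11))
            high = rng.uniform(0.6, 1.0, size=n)
            low = high * rng.uniform(0.5, 1.0, size=n)
            cfg = ThresholdConfig(method="exact")
            x_high, _ = adjust_rare_threshold(high, cfg)
            x_low, _ = adjust_rare_threshold(low, cfg)
            assert x_low <= x_high


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t_core": 0.0},
            {"t_rare": 1.0},
            {"t_core": 0.04, "t_rare": 0.05},
            {"alpha": 0.0},
            {"prior_a": 0.0},
            {"n_sims": 0},
            {"method": "magic"},
            {"fixed_theta": 1.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ThresholdConfig(**kwargs)

    def test_unadjusted_cutoffs_classical_rule(self):
        # core iff frequency >= 0.95, rare iff frequency < 0.05 at N=500
        x_core, x_rare = unadjusted_cutoffs(500, 0.95, 0.05)
        assert x_core == 474
        assert x_rare == 25
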