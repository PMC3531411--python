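import math

import numpy as np
import pytest
from scipy import stats

from micropop import (
    DropletSpec,
    InvalidParameterError,
    OutOfSupportError,
    ToleranceUnreachableError,
    UrnSpec,
    beta_binomial_cdf,
    beta_binomial_pmf,
    composition_cv,
    distribution_moments,
    enumerate_paths,
    final_size_distribution,
    final_size_moments,
    forward_dp,
    rationalize_rate_ratio,
    sample_limit_composition,
    simulate_scaled_composition,
    simulate_urn,
    solve_stopping_time,
    two_type_droplet,
    urn_from_rates,
    yield_map_cdf,
)


class TestBetaBinomial:
    def test_single_cell_inoculum_is_uniform(self):
        np.testing.assert_allclose(beta_binomial_pmf(np.arange(4), UrnSpec(1, 1, 3)), 0.25)

    def test_d2_enumeration_oracle(self):
        """(1,1) inoculum, 2 draws: 1/3 each on {0,1,2}."""
        np.testing.assert_allclose(beta_binomial_pmf(np.arange(3), UrnSpec(1, 1, 2)), 1 / 3)

    @pytest.mark.parametrize("a", [2, 3, 5])
    def test_symmetric_parameters_give_symmetric_pmf(self, a):
        p = beta_binomial_pmf(np.arange(8), UrnSpec(a, a, 7))
        np.testing.assert_allclose(p, p[::-1], rtol=1e-12)

    @pytest.mark.parametrize("a1,a2,D", [(1, 1, 10), (2, 5, 30), (4, 3, 100)])
    def test_matches_scipy_reference(self, a1, a2, D):
        """Independent cross-check against scipy's Beta-Binomial."""
        mine = beta_binomial_pmf(np.arange(D + 1), UrnSpec(a1, a2, D))
        ref = stats.betabinom(D, a1, a2).pmf(np.arange(D + 1))
        np.testing.assert_allclose(mine, ref, rtol=1e-10)
        assert mine.sum() == pytest.approx(1.0, abs=1e-12)

    def test_out_of_support(self):
        with pytest.raises(OutOfSupportError):
            beta_binomial_pmf(4, UrnSpec(1, 1, 3))

    def test_urn_invariants(self):
        with pytest.raises(InvalidParameterError):
            UrnSpec(0, 0, 3)
        with pytest.raises(InvalidParameterError):
            UrnSpec(1, 1, 3, reinforcement=(2, 4))  # not coprime


class TestCompositionCV:
    def test_single_cell_limit_is_inverse_sqrt3(self):
        _, limit = composition_cv(UrnSpec(1, 1, 100))
        assert limit == pytest.approx(1 / math.sqrt(3), rel=1e-12)

    def test_ratio_decreases_monotonically_to_limit(self):
        ratios = [composition_cv(UrnSpec(2, 2, D))[0] for D in (1, 4, 16, 64, 256)]
        _, limit = composition_cv(UrnSpec(2, 2, 1))
        assert all(a > b for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] == pytest.approx(limit, rel=1e-2)
        assert all(r > limit for r in ratios)

    def test_one_draw_matches_two_point_pmf(self):
        urn = UrnSpec(3, 2, 1)
        p1 = beta_binomial_pmf(1, urn)
        mean = p1
        var = p1 * (1 - p1)
        ratio, _ = composition_cv(urn)
        assert ratio == pytest.approx(math.sqrt(var) / mean, rel=1e-12)

    def test_symmetric_inoculum_limit_is_inverse_sqrt_n0_plus_1(self):
        for a in (1, 2, 4, 8, 16):
            _, limit = composition_cv(UrnSpec(a, a, 1))
            assert limit == pytest.approx(1 / math.sqrt(2 * a + 1), rel=1e-12)

    def test_asymptotic_inverse_sqrt_scaling(self):
        """At large symmetric inocula the limit CV decays with exponent -1/2."""
        a_vals = 2 ** np.arange(5, 13)
        cvs = [composition_cv(UrnSpec(int(a), int(a), 1))[1] for a in a_vals]
        slope = np.polyfit(np.log(2 * a_vals), np.log(cvs), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.01)


class TestRationalize:
    @pytest.mark.parametrize("ratio, expected", [(2.0, (1, 2)), (1.5, (2, 3)), (0.25, (4, 1))])
    def test_simple_ratios(self, ratio, expected):
        assert rationalize_rate_ratio(ratio, 1e-9) == expected

    def test_pi_convergent_satisfies_bound(self):
        k1, k2 = rationalize_rate_ratio(math.pi, 1e-4)
        assert abs(k2 / k1 - math.pi) <= 1e-4 * math.pi
        assert math.gcd(k1, k2) == 1
        # minimality: no smaller denominator achieves the bound
        for q in range(1, k1):
            assert abs(round(math.pi * q) / q - math.pi) > 1e-4 * math.pi

    def test_unreachable_tolerance(self):
        with pytest.raises(ToleranceUnreachableError):
            rationalize_rate_ratio(math.pi, 1e-16, max_denominator=1000)


class TestGeneralizedUrn:
    def test_urn_draw_counts_match_jump_chain_with_real_rates(self):
        """Reinforcement (1,2) urn vs jump chain at rate ratio 2: identical
        d1 laws (the urn is faithful to the division-rate odds)."""
        urn = urn_from_rates(1, 1, D=8, rate_ratio=2.0)
        assert urn.reinforcement == (1, 2)
        d1_urn = simulate_urn(urn, seed=41, n_reps=50_000)
        spec = DropletSpec.from_arrays(counts=(1, 1), rates=(1.0, 2.0), yields=(1.0, 1.0), budget=8.0)
        exact = forward_dp(spec)
        vals, probs = exact.marginal("d1")
        freqs = np.bincount(d1_urn, minlength=9) / 50_000
        se = np.sqrt(probs * (1 - probs) / 50_000)
        np.testing.assert_allclose(freqs[vals.astype(int)], probs, atol=3 * se.max() + 1e-9)


class TestLimitComposition:
    def test_rho1_law_is_exactly_beta(self, rng):
        """z = W1/(W1+W2) with Gamma(a_i) components is Beta(a1, a2)."""
        for a1, a2 in ((1, 1), (1, 3), (4, 2)):
            z = sample_limit_composition(a1, a2, 1.0, rng, size=20_000).z
            ks = stats.kstest(z, stats.beta(a1, a2).cdf)
            assert ks.pvalue > 0.01
            assert z.mean() == pytest.approx(a1 / (a1 + a2), abs=3 * z.std() / np.sqrt(20_000))

    def test_beta13_mean(self, rng):
        z = sample_limit_composition(1, 3, 1.0, rng, size=100_000).z
        assert z.mean() == pytest.approx(0.25, abs=3 * z.std() / math.sqrt(100_000))

    def test_empty_color_degenerates(self, rng):
        z = sample_limit_composition(0, 2, 1.0, rng, size=100).z
        np.testing.assert_array_equal(z, 0.0)

    def test_scaled_simulation_converges_to_beta_at_rho1(self):
        z = simulate_scaled_composition(2, 2, 1.0, n_divisions=2**12, seed=43, n_reps=5_000)
        ks = stats.kstest(z, stats.beta(2, 2).cdf)
        assert ks.pvalue > 0.01


class TestYieldMap:
    def test_equal_costs_identity(self, uniform_spec):
        """r=1: the map is the identity on the uniform problem."""
        spec = uniform_spec(4)
        urn = UrnSpec(1, 1, 4)
        for d1 in range(5):
            assert yield_map_cdf(d1, spec) == pytest.approx(beta_binomial_cdf(d1, urn), rel=1e-12)

    def test_toy_instance_cdf_matches_enumeration(self, toy_spec):
        exact = enumerate_paths(toy_spec)
        for d1 in range(4):
            assert yield_map_cdf(d1, toy_spec) == pytest.approx(exact.cdf("d1", d1), rel=1e-9)

    def test_max_support_cdf_is_one(self, toy_spec):
        assert yield_map_cdf(3, toy_spec) == pytest.approx(1.0)

    def test_out_of_support_signalled(self, toy_spec):
        with pytest.raises(OutOfSupportError):
            yield_map_cdf(5, toy_spec)

    def test_dp_backend_for_unequal_rates(self):
        """Unequal rates route through the uniform-cost lattice solver and
        stay within one division of the exact variable-yield law."""
        spec = DropletSpec.from_arrays(counts=(1, 1), rates=(1.0, 2.0), yields=(1.0, 0.5), budget=4.0)
        exact = forward_dp(spec)
        for d1 in range(5):
            approx = yield_map_cdf(d1, spec, backend="dp")
            lo = exact.cdf("d1", d1 - 1)
            hi = exact.cdf("d1", d1 + 1)
            assert lo - 1e-9 <= approx <= hi + 1e-9


class TestFinalSize:
    def test_equal_costs_point_mass(self, uniform_spec):
        nf, p = final_size_distribution(uniform_spec(4)).marginal("n_final")
        np.testing.assert_array_equal(nf, [6])
        assert p[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("backend", ["dp", "map"])
    def test_toy_size_law(self, toy_spec, backend):
        nf, p = final_size_distribution(toy_spec, backend=backend).marginal("n_final")
        np.testing.assert_array_equal(nf, [4, 5])
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-12)

    def test_tradeoff_monotone_transform(self, toy_spec):
        """cost2 > cost1: larger d1 means larger N_f along the stopping line."""
        dist = final_size_distribution(toy_spec)
        d1 = dist.d_counts[:, 0]
        nf = dist.n_final
        order = np.argsort(d1)
        assert np.all(np.diff(nf[order]) >= 0)

    def test_toy_moments(self, toy_spec):
        mean, var = final_size_moments(toy_spec)
        assert mean == pytest.approx(13 / 3, rel=1e-12)
        assert var == pytest.approx(2 / 9, rel=1e-12)

    def test_uniform_yield_zero_variance(self):
        spec = two_type_droplet(2, budget=10.0, rate_ratio=2.0, yield_ratio=1.0)
        _, var = final_size_moments(spec)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_variance_grows_with_yield_variability(self):
        """At fixed rates and budget, Var(N_f) increases monotonically as the
        yield ratio departs from 1."""
        variances = []
        for r in (1.0, 0.8, 0.5, 0.25):
            spec = two_type_droplet(2, budget=30.0, rate_ratio=2.0, yield_ratio=r)
            variances.append(final_size_moments(spec)[1])
        assert all(b > a for a, b in zip(variances, variances[1:]))

    def test_limit_backend_mean_matches_deterministic_at_large_inoculum(self):
        spec = two_type_droplet(128, budget=1000.0, rate_ratio=2.0, yield_ratio=0.5)
        mean, var = final_size_moments(spec, backend="limit", n_samples=40_000, seed=3)
        det = solve_stopping_time(spec).n_final
        se = math.sqrt(var / 40_000)
        assert mean == pytest.approx(det, abs=3 * se + 0.05 * math.sqrt(var))

    def test_mean_shift_sign_follows_yield_correlation(self):
        """Mean N_f sits above the uniform-yield baseline under tradeoff,
        below it under positive rate-yield correlation."""
        for r, sign in ((0.5, 1), (2.0, -1)):
            spec = two_type_droplet(2, budget=40.0, rate_ratio=2.0, yield_ratio=r)
            mean, _ = final_size_moments(spec)
            baseline = 2 + r * 40.0  # N0 + y2*S: all-fast-type consumption
            assert sign * (mean - baseline) > 0


def test_moments_cross_check_quadrature_vs_monte_carlo(toy_spec):
    """Exact lattice moments vs simulation moments on the toy instance."""
    from micropop import run_ensemble

    ens = run_ensemble(toy_spec, n_reps=50_000, seed=51)
    mean, var = final_size_moments(toy_spec)
    se = math.sqrt(var / 50_000)
    assert ens.mean_n_final == pytest.approx(mean, abs=3 * se)
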