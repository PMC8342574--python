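import math

import numpy as np
import pytest
from scipy import stats

from twinbiome.twin_model import (
    DegenerateDataError,
    PairedPhenotypes,
    VarianceComponents,
    compare,
    confidence_intervals,
    fit,
    heritability_test,
    implied_covariance,
    loglik,
    standardize,
)
from conftest import exact_moment_pairs


def mvn_loglik_oracle(components, data):
    """Independent likelihood route: explicit per-pair scipy densities."""
    total = 0.0
    mean = [components.mu, components.mu]
    for zyg, arr in (("MZ", data.mz), ("DZ", data.dz)):
        cov = implied_covariance(components, zyg)
        if arr.shape[0]:
            total += stats.multivariate_normal.logpdf(arr, mean=mean, cov=cov).sum()
    return total


def grid_search_ae(data, n_coarse=25, refinements=3):
    """Coarse-then-refined exhaustive search over (mu, a2, e2)."""
    allv = data.all_values()
    m, v = float(allv.mean()), float(allv.var())
    lo = np.array([m - 1.0, -1.5 * v, 0.02 * v])
    hi = np.array([m + 1.0, 1.5 * v, 3.0 * v])
    best = None
    for _ in range(refinements):
        grids = [np.linspace(lo[i], hi[i], n_coarse) for i in range(3)]
        for mu in grids[0]:
            for a2 in grids[1]:
                for e2 in grids[2]:
                    c = VarianceComponents(a2=a2, c2=0.0, e2=e2, mu=mu)
                    ll = loglik(c, data)
                    if best is None or ll > best[0]:
                        best = (ll, np.array([mu, a2, e2]))
        width = (hi - lo) / (n_coarse - 1)
        lo = best[1] - 3.0 * width
        hi = best[1] + 3.0 * width
        lo[2] = max(lo[2], 1e-6 * v)
    resolution = (hi - lo) / (n_coarse - 1)
    return best[1], resolution


def random_pairs(rng, n_mz=30, n_dz=30, a2=0.4, c2=0.0, e2=0.6, mu=1.0):
    def draw(n, r):
        cov = np.array([[a2 + c2 + e2, r * a2 + c2], [r * a2 + c2, a2 + c2 + e2]])
        return rng.multivariate_normal([mu, mu], cov, size=n)
    return PairedPhenotypes(mz=draw(n_mz, 1.0), dz=draw(n_dz, 0.5))


class TestImpliedCovariance:
    def test_mz_shares_all_genetic_variance(self):
        c = VarianceComponents(a2=1.0, c2=0.0, e2=1.0, mu=0.0)
        np.testing.assert_allclose(implied_covariance(c, "MZ"), [[2, 1], [1, 2]])

    def test_dz_shares_half(self):
        c = VarianceComponents(a2=1.0, c2=0.0, e2=1.0, mu=0.0)
        np.testing.assert_allclose(implied_covariance(c, "DZ"), [[2, 0.5], [0.5, 2]])

    def test_common_environment_is_zygosity_invariant(self):
        c = VarianceComponents(a2=0.0, c2=0.7, e2=0.3, mu=0.0)
        np.testing.assert_allclose(implied_covariance(c, "MZ"), [[1, 0.7], [0.7, 1]])
        np.testing.assert_allclose(
            implied_covariance(c, "MZ"), implied_covariance(c, "DZ")
        )


class TestLoglik:
    def test_standard_bivariate_normal_at_origin(self):
        data = PairedPhenotypes(mz=np.array([[0.0, 0.0]]), dz=np.empty((0, 2)))
        c = VarianceComponents(a2=0.0, c2=0.0, e2=1.0, mu=0.0)
        assert loglik(c, data) == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_within_pair_exchangeability(self, rng):
        data = random_pairs(rng)
        c = VarianceComponents(a2=0.3, c2=0.1, e2=0.6, mu=1.0)
        swapped = PairedPhenotypes(mz=data.mz[:, ::-1], dz=data.dz[:, ::-1])
        assert loglik(c, data) == pytest.approx(loglik(c, swapped), rel=1e-12)

    def test_matches_scipy_density_oracle(self, rng):
        data = random_pairs(rng, n_mz=12, n_dz=9)
        for a2, c2, e2, mu in [(0.4, 0.0, 0.6, 1.0), (0.1, 0.3, 0.5, 0.8), (-0.1, 0.2, 0.7, 1.2)]:
            c = VarianceComponents(a2=a2, c2=c2, e2=e2, mu=mu)
            assert loglik(c, data) == pytest.approx(mvn_loglik_oracle(c, data), rel=1e-10)

    def test_non_positive_definite_gives_minus_inf(self):
        data = PairedPhenotypes(mz=np.array([[0.0, 0.1]]), dz=np.empty((0, 2)))
        c = VarianceComponents(a2=2.0, c2=0.0, e2=0.1, mu=0.0)  # |off| > diag is impossible
        # off = 2.0, var = 2.1 is fine; make it degenerate instead
        c = VarianceComponents(a2=-3.0, c2=2.0, e2=0.5, mu=0.0)
        assert loglik(c, data) == -math.inf


class TestFit:
    def test_ae_recovers_exact_moments(self, exact_ae_data):
        res = fit(exact_ae_data, model="AE")
        assert res.converged
        assert res.components.a2 == pytest.approx(0.6, abs=1e-4)
        assert res.components.e2 == pytest.approx(0.4, abs=1e-4)
        assert res.components.mu == pytest.approx(0.0, abs=1e-4)
        assert res.standardized["A"] == pytest.approx(0.6, abs=1e-4)

    def test_equal_twin_correlations_force_a2_to_zero(self, equal_correlation_data):
        res = fit(equal_correlation_data, model="ACE")
        assert res.components.a2 == pytest.approx(0.0, abs=1e-3)
        assert res.components.c2 == pytest.approx(0.5, abs=1e-3)
        assert res.components.e2 == pytest.approx(0.5, abs=1e-3)

    def test_matches_grid_search_oracle_small_data(self, rng):
        data = random_pairs(rng, n_mz=20, n_dz=20)
        res = fit(data, model="AE")
        grid_est, resolution = grid_search_ae(data)
        est = np.array([res.components.mu, res.components.a2, res.components.e2])
        # estimates agree to within the grid's cell size, and the
        # optimizer is never beaten by the exhaustive search
        assert np.all(np.abs(est - grid_est) <= 2.0 * resolution)
        grid_ll = loglik(
            VarianceComponents(a2=grid_est[1], c2=0.0, e2=grid_est[2], mu=grid_est[0]),
            data,
        )
        assert res.loglik >= grid_ll - 1e-6

    def test_nesting_of_likelihoods(self, rng):
        data = random_pairs(rng, n_mz=60, n_dz=60)
        ll = {m: fit(data, model=m).loglik for m in ("ACE", "AE", "CE", "E")}
        assert ll["ACE"] >= ll["AE"] - 1e-6
        assert ll["AE"] >= ll["E"] - 1e-6
        assert ll["ACE"] >= ll["CE"] - 1e-6
        assert ll["CE"] >= ll["E"] - 1e-6

    def test_aic_identity_and_standardized_sum(self, rng):
        data = random_pairs(rng)
        for model in ("ACE", "AE", "CE", "E"):
            res = fit(data, model=model)
            assert res.aic == pytest.approx(-2 * res.loglik + 2 * res.n_params, abs=1e-12)
            assert sum(res.standardized.values()) == pytest.approx(1.0, abs=1e-8)

    def test_invariant_to_pair_permutation_and_member_swap(self, rng):
        data = random_pairs(rng, n_mz=25, n_dz=25)
        perm = rng.permutation(25)
        scrambled = PairedPhenotypes(mz=data.mz[perm][:, ::-1], dz=data.dz[:, ::-1])
        r1, r2 = fit(data, "AE"), fit(scrambled, "AE")
        assert r1.components.a2 == pytest.approx(r2.components.a2, abs=1e-6)
        assert r1.loglik == pytest.approx(r2.loglik, abs=1e-6)

    def test_path_parameterization_keeps_variances_nonnegative(self, rng):
        # negative within-pair covariances pull a2 below zero under the
        # direct parameterization; path must stay at the boundary
        data = PairedPhenotypes(
            mz=exact_moment_pairs(-0.3), dz=exact_moment_pairs(-0.15)
        )
        direct = fit(data, model="AE", parameterization="direct")
        constrained = fit(data, model="AE", parameterization="path")
        assert direct.components.a2 < 0
        assert constrained.components.a2 >= 0

    def test_degenerate_data_rejected(self):
        flat = PairedPhenotypes(mz=np.ones((5, 2)), dz=np.ones((5, 2)))
        with pytest.raises(DegenerateDataError):
            fit(flat, model="AE")
        tiny = PairedPhenotypes(mz=np.array([[0.0, 1.0]]), dz=np.array([[0.0, 1.0]]))
        with pytest.raises(DegenerateDataError):
            fit(tiny, model="ACE")


class TestStandardize:
    @pytest.mark.parametrize(
        "a2, e2, expected_a",
        [
            (0.1428, 0.2683, 0.3473),  # h2 = A / (A + E)
            (0.0455, 0.2213, 0.1706),
            (0.5, 0.5, 0.5),
        ],
    )
    def test_ae_standardization(self, a2, e2, expected_a):
        c = VarianceComponents(a2=a2, c2=0.0, e2=e2, mu=0.0)
        std = standardize(c, "AE")
        assert std["A"] == pytest.approx(expected_a, abs=5e-4)
        assert std["A"] + std["E"] == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_total_rejected(self):
        c = VarianceComponents(a2=-1.0, c2=0.0, e2=0.5, mu=0.0)
        with pytest.raises(DegenerateDataError):
            standardize(c, "AE")


class TestCompare:
    def test_identical_logliks_give_zero_statistic(self, rng):
        from dataclasses import replace

        data = random_pairs(rng)
        full = fit(data, "ACE")
        # a nested model that happens to reach the same likelihood
        red = replace(full, model="AE", n_params=full.n_params - 1)
        cmp_ = compare(full, red)
        assert cmp_.lr_stat == 0.0
        assert cmp_.p_value == pytest.approx(1.0)

    def test_lr_statistic_and_pvalues(self, exact_ae_data):
        full = fit(exact_ae_data, "AE")
        red = fit(exact_ae_data, "E")
        cmp_ = compare(full, red)
        assert cmp_.df == 1
        assert cmp_.lr_stat == pytest.approx(2 * (full.loglik - red.loglik), abs=1e-10)
        assert cmp_.p_value == pytest.approx(stats.chi2.sf(cmp_.lr_stat, 1), abs=1e-12)
        assert cmp_.delta_aic == pytest.approx(red.aic - full.aic, abs=1e-10)

    def test_non_nested_rejected(self, rng):
        data = random_pairs(rng)
        ae, ce = fit(data, "AE"), fit(data, "CE")
        with pytest.raises(ValueError):
            compare(ae, ce)


class TestConfidenceIntervals:
    def test_interval_brackets_estimate_and_e_positive(self, rng):
        data = random_pairs(rng, n_mz=200, n_dz=200)
        res = fit(data, "AE")
        ci = confidence_intervals(res, data)
        lo_a, hi_a = ci["A"]
        assert lo_a <= res.components.a2 <= hi_a
        lo_e, hi_e = ci["E"]
        assert 0.0 < lo_e <= res.components.e2 <= hi_e

    def test_width_shrinks_with_sample_size(self):
        widths = []
        for n in (100, 1000, 10000):
            rng = np.random.default_rng(5)
            data = random_pairs(rng, n_mz=n, n_dz=n)
            res = fit(data, "AE")
            lo, hi = confidence_intervals(res, data)["A"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_wald_close_to_profile_at_large_n(self, rng):
        data = random_pairs(rng, n_mz=2000, n_dz=2000)
        res = fit(data, "AE")
        prof = confidence_intervals(res, data, method="profile")["A"]
        wald = confidence_intervals(res, data, method="wald")["A"]
        assert prof[0] == pytest.approx(wald[0], abs=0.02)
        assert prof[1] == pytest.approx(wald[1], abs=0.02)


class TestHeritabilityTest:
    def test_reports_ae_h2_and_nested_ladder(self, rng):
        data = random_pairs(rng, n_mz=400, n_dz=400, a2=0.4, e2=0.6)
        h2, p, fits = heritability_test(data)
        assert set(fits) == {"ACE", "AE", "CE", "E"}
        assert h2 == fits["AE"].standardized["A"]
        assert 0 <= p <= 1

    def test_parameter_recovery_at_scale(self):
        rng = np.random.default_rng(1234)
        data = random_pairs(rng, n_mz=5000, n_dz=5000, a2=0.347, e2=0.653, mu=0.8)
        h2, p, _ = heritability_test(data)
        assert h2 == pytest.approx(0.347, abs=0.03)
        assert p < 0.001
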