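"""PSA distributions, correlated draws, CEAC and tornado analysis."""

import copy

import numpy as np
import pytest
import scipy.stats as ss

import htnscreen as h
from htnscreen.uncertainty import default_sa_plan

SEED = 20260930


class TestMomentMatching:
    def test_gamma_hand_example(self):
        shape, scale = h.gamma_from_moments(70.82, 17.705)
        assert shape == pytest.approx(16.0, rel=1e-12)
        assert scale == pytest.approx(4.42625, rel=1e-12)

    def test_gamma_unit_exponential(self):
        assert h.gamma_from_moments(1.0, 1.0) == (1.0, 1.0)

    def test_gamma_moments_recovered_analytically(self):
        shape, scale = h.gamma_from_moments(6.05, 1.5125)
        dist = ss.gamma(shape, scale=scale)
        assert dist.mean() == pytest.approx(6.05, rel=1e-12)
        assert dist.std() == pytest.approx(1.5125, rel=1e-12)

    def test_beta_hand_example(self):
        a, b = h.beta_from_moments(0.93, 0.0465)
        assert a + b == pytest.approx(0.93 * 0.07 / 0.0465**2 - 1, rel=1e-12)
        assert a == pytest.approx(27.07, abs=0.01)
        dist = ss.beta(a, b)
        assert dist.mean() == pytest.approx(0.93, rel=1e-12)
        assert dist.std() == pytest.approx(0.0465, rel=1e-12)

    def test_beta_symmetric_at_half(self):
        a, b = h.beta_from_moments(0.5, 0.1)
        assert a == pytest.approx(b)

    def test_beta_infeasible_variance_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            h.beta_from_moments(0.9, 0.5)

    def test_lognormal_median_anchored(self):
        mu, sigma = h.lognormal_from_rr(0.72, 0.1)
        assert mu == pytest.approx(np.log(0.72), rel=1e-12)
        assert sigma == 0.1
        assert h.lognormal_from_rr(1.0, 0.3)[0] == 0.0

    def test_lognormal_rejects_nonpositive_rr(self):
        with pytest.raises(ValueError):
            h.lognormal_from_rr(-0.5, 0.1)


class TestCholesky:
    def test_identity(self):
        np.testing.assert_allclose(h.cholesky_factor(np.eye(3)), np.eye(3))

    def test_hand_factorization(self):
        L = h.cholesky_factor(np.array([[4.0, 2.0], [2.0, 3.0]]))
        np.testing.assert_allclose(L, [[2.0, 0.0], [1.0, np.sqrt(2.0)]], atol=1e-12)

    def test_reconstruction_residual_on_random_psd(self, rng):
        for _ in range(20):
            A = rng.standard_normal((4, 4))
            cov = A @ A.T + 1e-6 * np.eye(4)
            L = h.cholesky_factor(cov)
            assert np.abs(L @ L.T - cov).max() < 1e-10
            assert np.allclose(np.triu(L, 1), 0.0)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError, match="semi-definite"):
            h.cholesky_factor(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            h.cholesky_factor(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestDrawParameters:
    def test_same_seed_identical_draws(self, params):
        a = h.draw_parameters(params, 42)
        b = h.draw_parameters(params, 42)
        assert h.params_equal(a, b)

    def test_fixed_specs_pass_through(self, params):
        p2 = copy.deepcopy(params)
        p2.psa = {k: h.DistributionSpec("fixed", v.mean, v.se)
                  for k, v in p2.psa.items()}
        assert h.params_equal(h.draw_parameters(p2, 1), p2)

    def test_sample_means_match_specs(self, params):
        n = 3000
        rng = np.random.default_rng(SEED)
        draws = {"econ.cost_htn_treat_year": np.empty(n),
                 "econ.utility_healthy": np.empty(n)}
        for i in range(n):
            dp = h.draw_parameters(params, rng)
            draws["econ.cost_htn_treat_year"][i] = dp.econ.cost_htn_treat_year
            draws["econ.utility_healthy"][i] = dp.econ.utility_healthy
        for name, arr in draws.items():
            spec = params.psa[name]
            se_mean = spec.se / np.sqrt(n)
            assert abs(arr.mean() - spec.mean) < 3 * se_mean

    def test_coefficient_draws_recover_covariance(self, params):
        n = 4000
        rng = np.random.default_rng(SEED)
        vecs = np.empty((n, 4))
        for i in range(n):
            dp = h.draw_parameters(params, rng)
            vecs[i] = dp.risk.mean_vector()
        cov_hat = np.cov(vecs.T)
        cov = np.asarray(params.risk.covariance)
        # diagonal recovered within Monte Carlo tolerance
        se_var = np.sqrt(2.0 / (n - 1)) * np.diag(cov)
        assert np.all(np.abs(np.diag(cov_hat) - np.diag(cov)) < 4 * se_var)
        mean_hat = vecs.mean(axis=0)
        se_mean = np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(mean_hat - params.risk.mean_vector()) < 4 * se_mean)

    def test_missing_spec_fields_rejected(self, params):
        p2 = copy.deepcopy(params)
        p2.psa["econ.cost_screen_round"] = h.DistributionSpec("gamma")
        with pytest.raises(ValueError, match="cost_screen_round"):
            h.draw_parameters(p2, 0)


class TestRunPsa:
    def test_all_fixed_reproduces_deterministic(self, params, scenario_m55,
                                                comparator_m55):
        p2 = copy.deepcopy(params)
        p2.psa = {k: h.DistributionSpec("fixed", v.mean, v.se)
                  for k, v in p2.psa.items()}
        det = [h.accrue(h.run_cohort(s, p2), p2.econ)
               for s in (comparator_m55, scenario_m55)]
        sample = h.run_psa([comparator_m55, scenario_m55], p2, n=1, seed=5)
        assert sample.costs[0, 0] == det[0].total_cost
        assert sample.qalys[0, 1] == det[1].total_qaly

    def test_same_seed_identical_samples(self, params, scenario_m55,
                                         comparator_m55):
        scens = [comparator_m55, scenario_m55]
        a = h.run_psa(scens, params, n=20, seed=9)
        b = h.run_psa(scens, params, n=20, seed=9)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)

    def test_draws_are_finite_and_counted(self, params, scenario_m55,
                                          comparator_m55):
        sample = h.run_psa([comparator_m55, scenario_m55], params, n=30, seed=2)
        assert sample.n_draws == 30
        assert np.all(np.isfinite(sample.costs)) and np.all(np.isfinite(sample.qalys))


class TestCeac:
    def _sample(self, de, dc):
        """Synthetic two-strategy PSA sample with given increments."""
        n = len(de)
        s0 = h.Scenario(sex="male", start_age=55, strategy="none")
        s1 = h.Scenario(sex="male", start_age=55, strategy="one_off")
        costs = np.column_stack([np.zeros(n), dc])
        qalys = np.column_stack([np.zeros(n), de])
        return h.PSASample(scenarios=[s0, s1], costs=costs, qalys=qalys,
                           seed=0, specs={})

    def test_all_dominant_draws_curve_is_one(self):
        sample = self._sample(de=np.ones(50), dc=-np.ones(50))
        curve = h.ceac(sample, "one_off", "none", np.array([0.0, 1e4, 1e6]))
        np.testing.assert_array_equal(curve.probability, 1.0)

    def test_zero_threshold_counts_cost_saving_draws(self, rng):
        dc = rng.standard_normal(400)
        sample = self._sample(de=np.ones(400), dc=dc)
        curve = h.ceac(sample, "one_off", "none", np.array([0.0, 1.0]))
        assert curve.probability[0] == pytest.approx((dc <= 0).mean())

    def test_nondecreasing_when_gains_positive(self, params, scenario_m55,
                                               comparator_m55):
        sample = h.run_psa([comparator_m55, scenario_m55], params, n=60, seed=3)
        grid = h.default_wtp_grid(params)
        curve = h.ceac(sample, "one_off", "none", grid)
        assert np.all(curve.probability >= 0.0) and np.all(curve.probability <= 1.0)
        de = sample.qalys[:, 1] - sample.qalys[:, 0]
        if np.all(de >= 0):
            assert np.all(np.diff(curve.probability) >= -1e-12)

    def test_bad_grid_rejected(self):
        sample = self._sample(np.ones(3), np.ones(3))
        with pytest.raises(ValueError, match="grid"):
            h.ceac(sample, "one_off", "none", np.array([1.0, 1.0]))


@pytest.fixture(scope="module")
def tornado(params):
    scen = h.Scenario(sex="male", start_age=55, strategy="biannual")
    return scen, h.univariate_sa(scen, params)


class TestUnivariateSa:
    def test_null_perturbation_equals_base_icer(self, params, tornado):
        scen, df = tornado
        base_row = df[df["perturbation"] == "base_case"].iloc[0]
        comp = h.Scenario(sex="male", start_age=55, strategy="none")
        expected = h.icer(h.accrue(h.run_cohort(scen, params), params.econ),
                          h.accrue(h.run_cohort(comp, params), params.econ))
        assert base_row["icer"] == pytest.approx(expected.value, rel=1e-12)

    def test_screening_cost_increase_raises_icer(self, tornado):
        _, df = tornado
        base = df[df["perturbation"] == "base_case"]["icer"].iloc[0]
        up = df[df["perturbation"] == "cost_screen_+25pct"]["icer"].iloc[0]
        down = df[df["perturbation"] == "cost_screen_-25pct"]["icer"].iloc[0]
        assert down < base < up

    def test_qaly_discounting_weakly_raises_icer(self, tornado):
        _, df = tornado
        base = df[df["perturbation"] == "base_case"]["icer"].iloc[0]
        d3 = df[df["perturbation"] == "discount_qaly_3pct"]["icer"].iloc[0]
        d1 = df[df["perturbation"] == "discount_qaly_1pct"]["icer"].iloc[0]
        assert base <= d1 <= d3

    def test_plan_rows_present_and_ordered(self, tornado):
        _, df = tornado
        assert set(default_sa_plan()) == set(df["perturbation"])
        assert df["perturbation"].iloc[0] == "base_case"
        shifts = df["abs_shift"].iloc[1:].to_numpy()
        assert np.all(np.diff(shifts[~np.isnan(shifts)]) <= 1e-9)

    def test_gbd_utilities_row_differs_from_base(self, tornado):
        _, df = tornado
        gbd = df[df["perturbation"] == "gbd_utilities"]["icer"].iloc[0]
        base = df[df["perturbation"] == "base_case"]["icer"].iloc[0]
        assert gbd != base

    def test_unknown_perturbation_rejected(self, params):
        scen = h.Scenario(sex="male", start_age=55, strategy="one_off")
        with pytest.raises(ValueError, match="unknown perturbation"):
            h.univariate_sa(scen, params, plan={"base_case": {}, "bogus": "???"})
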