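"""Semivariogram estimation, model fitting, and kriging systems."""

import numpy as np
import pytest

from pmsurface.errors import DomainError, ValidationError
from pmsurface.geostat import (EmpiricalVariogram, KrigingConfig, VariogramModel,
                               empirical_semivariogram, fit_variogram,
                               kriging_predict, variogram_eval)
from pmsurface.synthetic_data import SimulationConfig, simulate_grf


class TestEmpiricalVariogram:
    def test_two_station_single_bin_matheron(self):
        emp = empirical_semivariogram([(0, 0), (1, 0)], [1.0, 3.0],
                                      n_lags=1, max_dist=2.0)
        # (1 / (2*1)) * (3 - 1)^2 = 2
        assert emp.semivariances[0] == pytest.approx(2.0)
        assert emp.pair_counts[0] == 1

    def test_constant_field_gives_zero_semivariance(self, rng):
        locations = rng.uniform(0, 100, (15, 2))
        emp = empirical_semivariogram(locations, np.full(15, 7.0))
        np.testing.assert_array_equal(emp.semivariances, 0.0)

    def test_short_lags_below_long_lags_on_smooth_field(self, gaussian_variogram):
        cfg = SimulationConfig(n_stations=100, bbox=(0, 1000, 0, 1000),
                               variogram=gaussian_variogram, seed=11, value_floor=50.0)
        st = simulate_grf(cfg)
        emp = empirical_semivariogram(*st.pollutant_data("pm25"))
        near = emp.semivariances[emp.lag_centers < 0.2 * gaussian_variogram.range_]
        far = emp.semivariances[emp.lag_centers > 0.9 * gaussian_variogram.range_]
        assert near.mean() < far.mean()

    def test_all_pairs_beyond_max_dist_is_an_error(self):
        with pytest.raises(ValidationError, match="beyond max_dist"):
            empirical_semivariogram([(0, 0), (100, 0)], [1.0, 2.0],
                                    n_lags=3, max_dist=1.0)


class TestVariogramEval:
    def test_sill_reached_at_large_lag(self):
        m = VariogramModel("gaussian", nugget=0.3, partial_sill=2.0, range_=10.0)
        assert variogram_eval(m, 1000.0) == pytest.approx(2.3, abs=1e-9)

    def test_stable_with_exponent_two_equals_gaussian(self):
        h = np.linspace(0.0, 50.0, 200)
        g = VariogramModel("gaussian", 0.2, 1.5, 12.0)
        s = VariogramModel("stable", 0.2, 1.5, 12.0, shape=2.0)
        np.testing.assert_allclose(variogram_eval(s, h), variogram_eval(g, h))

    def test_hole_effect_at_half_range_hits_the_sill(self):
        # sin(pi)/pi = 0, so gamma(a/2) = c0 + c
        m = VariogramModel("hole_effect", nugget=0.1, partial_sill=1.0, range_=8.0)
        assert variogram_eval(m, 4.0) == pytest.approx(1.1, abs=1e-12)

    def test_zero_lag_is_zero_and_nugget_is_a_jump(self):
        m = VariogramModel("j_bessel", nugget=0.5, partial_sill=1.0, range_=5.0)
        assert variogram_eval(m, 0.0) == 0.0
        assert variogram_eval(m, 1e-9) == pytest.approx(0.5, abs=1e-6)

    def test_negative_lag_rejected(self):
        m = VariogramModel("gaussian", 0.0, 1.0, 5.0)
        with pytest.raises(DomainError):
            variogram_eval(m, -1.0)


class TestFitVariogram:
    def test_recovers_exact_gaussian_model(self):
        truth = VariogramModel("gaussian", nugget=0.2, partial_sill=1.8, range_=700.0)
        h = np.linspace(50.0, 1500.0, 12)
        emp = EmpiricalVariogram(h, variogram_eval(truth, h), np.full(12, 30))
        fit = fit_variogram(emp, "gaussian")
        assert fit.nugget == pytest.approx(0.2, abs=0.02)
        assert fit.partial_sill == pytest.approx(1.8, rel=0.01)
        assert fit.range_ == pytest.approx(700.0, rel=0.01)

    def test_two_bins_insufficient(self):
        emp = EmpiricalVariogram(np.array([1.0, 2.0]), np.array([0.5, 0.8]),
                                 np.array([4, 4]))
        with pytest.raises(ValidationError, match="3 lag bins"):
            fit_variogram(emp, "gaussian")

    def test_simulation_recovery_of_range(self):
        truth = VariogramModel("gaussian", nugget=0.1, partial_sill=1.0, range_=2000.0)
        fitted = []
        for seed in range(20):
            cfg = SimulationConfig(n_stations=200, bbox=(0, 10000, 0, 10000),
                                   variogram=truth, seed=seed, value_floor=50.0)
            st = simulate_grf(cfg)
            emp = empirical_semivariogram(*st.pollutant_data("pm25"))
            fitted.append(fit_variogram(emp, "gaussian").range_)
        assert np.mean(fitted) == pytest.approx(2000.0, rel=0.30)


class TestKriging:
    def test_symmetric_layout_predicts_the_mean(self, gaussian_variogram):
        # layout symmetric under x -> 10 - x, which swaps the two stations
        # with values 10 and 30 and fixes the third (value 20 = their mean):
        # unbiasedness + symmetry force the prediction at (5, 0) to be 20
        locations = [(0.0, 0.0), (10.0, 0.0), (5.0, 40.0)]
        values = [10.0, 30.0, 20.0]
        pred, _ = kriging_predict(locations, values, [(5.0, 0.0)],
                                  KrigingConfig(gaussian_variogram))
        assert pred[0] == pytest.approx(20.0, abs=1e-10)

    def test_weights_sum_to_one(self, scattered, gaussian_variogram):
        # enforced through the Lagrange constraint: prediction of a constant
        # field must return the constant
        locations, _ = scattered
        values = np.full(len(locations), 13.5)
        pred, _ = kriging_predict(locations[:5], values[:5],
                                  [(500.0, 500.0), (-100.0, 0.0)],
                                  KrigingConfig(gaussian_variogram))
        np.testing.assert_allclose(pred, 13.5, rtol=1e-8)

    def test_matches_independent_dense_solve(self, gaussian_variogram, rng):
        from scipy.spatial.distance import cdist
        locations = rng.uniform(0, 500, (4, 2))
        values = rng.uniform(5, 25, 4)
        target = np.array([[200.0, 250.0]])
        pred, _ = kriging_predict(locations, values, target,
                                  KrigingConfig(gaussian_variogram))
        # independent assembly of the augmented OK system
        gamma = variogram_eval(gaussian_variogram, cdist(locations, locations))
        a = np.block([[gamma, np.ones((4, 1))], [np.ones((1, 4)), np.zeros((1, 1))]])
        rhs = np.concatenate(
            [variogram_eval(gaussian_variogram, cdist(locations, target))[:, 0], [1.0]])
        lam = np.linalg.solve(a, rhs)[:4]
        assert pred[0] == pytest.approx(float(lam @ values), abs=1e-10)

    def test_exact_at_data_sites_without_nugget(self, scattered, gaussian_variogram):
        locations, values = scattered
        pred, var = kriging_predict(locations, values, locations,
                                    KrigingConfig(gaussian_variogram))
        np.testing.assert_allclose(pred, values, rtol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)

    def test_nugget_makes_data_site_prediction_inexact(self, scattered):
        locations, values = scattered
        noisy = VariogramModel("gaussian", nugget=0.5, partial_sill=1.0, range_=300.0)
        pred, var = kriging_predict(locations, values, locations, KrigingConfig(noisy))
        assert np.max(np.abs(pred - values)) > 1e-6
        assert np.all(var >= 0)

    def test_universal_drift_order_zero_equals_ordinary(self, scattered, gaussian_variogram):
        locations, values = scattered
        targets = np.array([[100.0, 900.0], [500.0, 500.0], [-50.0, 200.0]])
        p_ok, v_ok = kriging_predict(locations, values, targets,
                                     KrigingConfig(gaussian_variogram, "ordinary"))
        p_uk, v_uk = kriging_predict(locations, values, targets,
                                     KrigingConfig(gaussian_variogram, "universal", 0))
        np.testing.assert_allclose(p_ok, p_uk, atol=1e-10)
        np.testing.assert_allclose(v_ok, v_uk, atol=1e-10)

    def test_nearest_station_gets_largest_weight_on_transect(self, gaussian_variogram):
        # screening: for a gaussian model on a transect the closest station
        # dominates the weight vector
        locations = [(float(x), 0.0) for x in (0, 100, 200, 300, 400)]
        values = [1.0, 2.0, 3.0, 4.0, 5.0]
        from scipy.spatial.distance import cdist
        target = [(90.0, 0.0)]
        gamma = variogram_eval(gaussian_variogram,
                               cdist(np.asarray(locations), np.asarray(locations)))
        a = np.block([[gamma, np.ones((5, 1))], [np.ones((1, 5)), np.zeros((1, 1))]])
        rhs = np.concatenate(
            [variogram_eval(gaussian_variogram,
                            cdist(np.asarray(locations), np.asarray(target)))[:, 0], [1.0]])
        lam = np.linalg.solve(a, rhs)[:5]
        assert np.argmax(np.abs(lam)) == 1  # station at x=100 is nearest to x=90

    def test_fewer_than_three_stations_rejected(self, gaussian_variogram):
        with pytest.raises(ValidationError):
            kriging_predict([(0, 0), (1, 1)], [1.0, 2.0], [(0.5, 0.5)],
                            KrigingConfig(gaussian_variogram))
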