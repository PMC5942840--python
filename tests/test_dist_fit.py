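"""Pooling, three-parameter Weibull fitting and constrained sampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from facefem import dist_fit


def _weibull_samples(shape, scale, loc, n, seed):
    return stats.weibull_min(shape, loc=loc, scale=scale).rvs(
        n, random_state=np.random.default_rng(seed)
    )


class TestPooling:
    def _set(self, cols, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.uniform(size=(n, len(cols))), columns=cols)

    def test_five_sets_of_100_give_500_rows(self):
        cols = ["E_cart", "E_soft", "nu_soft", "G_scale"]
        sets = [self._set(cols, 100, seed=i) for i in range(5)]
        pooled = dist_fit.pool_candidates(sets)
        assert pooled.shape == (500, 4)
        assert list(pooled.columns) == cols
        pd.testing.assert_frame_equal(
            pooled.iloc[100:200].reset_index(drop=True), sets[1]
        )

    def test_single_set_identity(self):
        s = self._set(["a", "b"], 30)
        pd.testing.assert_frame_equal(dist_fit.pool_candidates([s]), s)

    def test_permuted_columns_raise(self):
        a = self._set(["a", "b"], 10)
        b = self._set(["b", "a"], 10)
        with pytest.raises(ValueError, match="mismatch"):
            dist_fit.pool_candidates([a, b])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dist_fit.pool_candidates([])


class TestFitWeibull:
    def test_parameter_recovery_at_origin(self):
        x = _weibull_samples(2.0, 1.0, 0.0, 500, seed=1)
        fit = dist_fit.fit_weibull(x, bounds=(0.0, 5.0))
        assert 1.8 <= fit.shape <= 2.2
        assert 0.93 <= fit.scale <= 1.07
        assert fit.n == 500

    def test_shifted_location_recovery(self):
        """Narrow shifted variable (Poisson-ratio-like support)."""
        x = _weibull_samples(2.0, 0.03, 0.45, 500, seed=2)
        fit = dist_fit.fit_weibull(x, bounds=(0.45, 0.499))
        assert abs(fit.location - 0.45) <= 0.01

    def test_constant_samples_raise(self):
        with pytest.raises(ValueError, match="constant"):
            dist_fit.fit_weibull(np.full(100, 1.0))

    def test_too_few_samples_advise_pooling(self):
        with pytest.raises(ValueError, match="pool"):
            dist_fit.fit_weibull(np.arange(10.0))

    def test_location_below_sample_minimum_and_valid_density(self):
        x = _weibull_samples(1.5, 2.0, 3.0, 200, seed=3)
        fit = dist_fit.fit_weibull(x, bounds=(0.0, 20.0))
        assert fit.location < x.min()
        # density integrates to ~1 over (location, inf)
        grid = np.linspace(fit.location, fit.location + 40 * fit.scale, 20000)
        pdf = fit.frozen().pdf(grid)
        assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-3)

    def test_round_trip_fit_sample_refit(self):
        fit = dist_fit.WeibullFit(shape=2.5, scale=0.8, location=1.0, n=0, ks=0.0)
        x = dist_fit.sample_distribution(fit, 500, seed=4)
        refit = dist_fit.fit_weibull(x, bounds=(1.0, 10.0))
        assert abs(refit.shape - 2.5) / 2.5 < 0.15
        assert abs(refit.scale - 0.8) / 0.8 < 0.15

    def test_ks_statistic_reasonable_for_true_model(self):
        x = _weibull_samples(2.0, 1.0, 0.0, 500, seed=5)
        fit = dist_fit.fit_weibull(x, bounds=(0.0, 5.0))
        # 5 % KS critical value at n=500 is ~0.0607
        assert fit.ks < 0.0607


class TestSampleDistribution:
    def test_mean_matches_analytic_moment(self):
        fit = dist_fit.WeibullFit(shape=2.0, scale=1.0, location=0.5, n=0, ks=0.0)
        x = dist_fit.sample_distribution(fit, 100_000, seed=6)
        assert np.mean(x) == pytest.approx(fit.mean(), rel=0.01)

    def test_deterministic_per_seed(self):
        fit = dist_fit.WeibullFit(shape=1.2, scale=2.0, location=0.0, n=0, ks=0.0)
        a = dist_fit.sample_distribution(fit, 100, seed=7)
        b = dist_fit.sample_distribution(fit, 100, seed=7)
        assert np.array_equal(a, b)

    def test_full_support_bounds_reject_nothing(self):
        fit = dist_fit.WeibullFit(shape=2.0, scale=1.0, location=0.0, n=0, ks=0.0)
        a = dist_fit.sample_distribution(fit, 500, seed=8)
        b = dist_fit.sample_distribution(fit, 500, bounds=(0.0, np.inf), seed=8)
        assert np.array_equal(a, b)

    def test_bounds_enforced(self):
        fit = dist_fit.WeibullFit(shape=2.0, scale=1.0, location=0.0, n=0, ks=0.0)
        x = dist_fit.sample_distribution(fit, 2000, bounds=(0.5, 1.5), seed=9)
        assert x.min() >= 0.5 and x.max() <= 1.5

    def test_bounds_excluding_all_mass_raise(self):
        fit = dist_fit.WeibullFit(shape=2.0, scale=1.0, location=0.0, n=0, ks=0.0)
        with pytest.raises(ValueError, match="mass"):
            dist_fit.sample_distribution(fit, 10, bounds=(50.0, 60.0), seed=0)

    def test_stratified_unit_samples_honour_bounds(self):
        fit = dist_fit.WeibullFit(shape=2.0, scale=1.0, location=0.0, n=0, ks=0.0)
        u = (np.arange(20) + 0.5) / 20
        x = dist_fit.sample_distribution(fit, 20, bounds=(0.5, 1.5), unit_samples=u)
        assert x.min() >= 0.5 and x.max() <= 1.5
        assert np.all(np.diff(x) > 0)  # monotone in the uniforms
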