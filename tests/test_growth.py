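"""Four-parameter logistic growth fits and RGR at a common size."""

import math

import numpy as np
import pytest

import yieldparts as yp
from yieldparts.growth import (FourParamLogistic, GrowthFitError, GrowthSeries,
                               common_size, read_growth_table,
                               write_growth_table)

DAYS = np.repeat([8.0, 12.0, 15.0, 19.0, 22.0, 26.0], 2)


def logistic(t, A, B, t_mid, s):
    return A + (B - A) / (1 + np.exp((t_mid - t) / s))


class TestFit:
    def test_noiseless_recovery_to_1e6(self):
        A, B, tm, s = -4.0, 1.0, 15.0, 4.0
        fit = FourParamLogistic().fit(DAYS, logistic(DAYS, A, B, tm, s))
        assert fit.A_ == pytest.approx(A, abs=1e-6)
        assert fit.B_ == pytest.approx(B, abs=1e-6)
        assert fit.t_mid_ == pytest.approx(tm, abs=1e-6)
        assert fit.s_ == pytest.approx(s, abs=1e-6)
        assert fit.converged_ and fit.rss_ < 1e-12

    def test_noisy_parameter_recovery_median_within_10pct(self):
        # simulation oracle: sigma=0.1 on ln mass, n=12, 100 replicates.
        # Asymptote errors are measured relative to the span B-A, the only
        # unit-invariant scale for ln-mass asymptotes.
        A, B, tm, s = -4.0, 1.0, 15.0, 4.0
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = logistic(DAYS, A, B, tm, s) + rng.normal(0, 0.1, DAYS.size)
            f = FourParamLogistic().fit(DAYS, y)
            errs.append([abs(f.A_ - A) / (B - A), abs(f.B_ - B) / (B - A),
                         abs(f.t_mid_ - tm) / tm, abs(f.s_ - s) / s])
        med = np.median(errs, axis=0)
        assert np.all(med < 0.10)

    def test_decreasing_series_is_error_not_inverted_fit(self):
        with pytest.raises(GrowthFitError, match="not increasing"):
            FourParamLogistic().fit(DAYS, logistic(DAYS, 1.0, -4.0, 15.0, 4.0))

    def test_flat_series_is_error(self):
        with pytest.raises(GrowthFitError, match="flat"):
            FourParamLogistic().fit(DAYS, np.full(DAYS.size, -2.0))

    def test_too_few_observations(self):
        with pytest.raises(GrowthFitError):
            FourParamLogistic().fit([8, 12, 15, 19], [-4, -3, -2, -1])

    def test_fitted_curve_monotone_increasing(self):
        rng = np.random.default_rng(3)
        y = logistic(DAYS, -4, 1, 15, 4) + rng.normal(0, 0.1, DAYS.size)
        fit = FourParamLogistic().fit(DAYS, y)
        grid = fit.predict(np.linspace(0, 40, 200))
        assert np.all(np.diff(grid) > 0)
        assert fit.B_ > fit.A_ and fit.s_ > 0


class TestRgrAtSize:
    @pytest.fixture()
    def fit(self):
        f = FourParamLogistic()
        f.A_, f.B_, f.t_mid_, f.s_ = -4.0, 1.0, 15.0, 4.0
        f.rss_, f.converged_, f.n_obs_ = 0.0, True, 12
        return f

    def test_inflection_gives_maximum_slope(self, fit):
        # p* = 1/2 at ln M = (A+B)/2: lambda_s = (B-A)/(4s)
        mc = math.exp((fit.A_ + fit.B_) / 2) * 1000.0
        est = fit.rgr_at_size(mc)
        assert est.lambda_s == pytest.approx((fit.B_ - fit.A_) / (4 * fit.s_), rel=1e-12)
        assert est.t_star == pytest.approx(fit.t_mid_, abs=1e-9)

    def test_closed_form_example(self):
        f = FourParamLogistic()
        f.A_, f.B_, f.t_mid_, f.s_ = -4.0, 1.0, 15.0, 4.0
        mc = math.exp(-1.5) * 1000.0  # midpoint of (A, B): p* = 0.5
        assert f.rgr_at_size(mc).lambda_s == pytest.approx(5.0 / 16.0, rel=1e-12)

    def test_closed_form_matches_numeric_slope(self, fit):
        est = fit.rgr_at_size(42.1)
        h = 1e-6
        numeric = (fit.predict(est.t_star + h) - fit.predict(est.t_star - h)) / (2 * h)
        assert est.lambda_s == pytest.approx(float(numeric), abs=1e-8)

    def test_size_outside_fitted_range_rejected(self, fit):
        with pytest.raises(GrowthFitError, match="outside fitted range"):
            fit.rgr_at_size(math.exp(fit.B_) * 1000.0 * 2)

    def test_unit_invariance_of_lambda_s(self):
        # fitting in mg shifts A and B by ln 1000 but leaves lambda_s alone
        A, B, tm, s = -4.0, 1.0, 15.0, 4.0
        y_g = logistic(DAYS, A, B, tm, s)
        fit_g = FourParamLogistic().fit(DAYS, y_g)
        fit_mg = FourParamLogistic().fit(DAYS, y_g + math.log(1000.0))
        lam_g = fit_g.rgr_at_size(42.1).lambda_s
        p = (math.log(42.1) - fit_mg.A_) / (fit_mg.B_ - fit_mg.A_)  # 42.1 mg directly
        lam_mg = (fit_mg.B_ - fit_mg.A_) * p * (1 - p) / fit_mg.s_
        assert lam_g == pytest.approx(lam_mg, rel=1e-6)

    def test_exponential_phase_limit_recovers_rate(self):
        # a logistic with a very wide span sampled near its inflection is
        # indistinguishable from exponential growth at rate r = (B-A)/(4s);
        # lambda_s at a size inside the sampled window recovers r within 3%
        r = 0.25
        A, B, tm = -18.0, 18.0, 15.0
        s = (B - A) / (4 * r)  # 36
        t = np.linspace(2, 30, 12)
        y = logistic(t, A, B, tm, s)
        fit = FourParamLogistic().fit(t, y)
        target_ln = float(logistic(12.0, A, B, tm, s))
        est = fit.rgr_at_size(math.exp(target_ln) * 1000.0)
        assert est.lambda_s == pytest.approx(r, rel=0.03)


class TestCommonSize:
    def _series(self, species, first_masses, later=1.0):
        obs = [(8.0, m, "g1") for m in first_masses]
        obs += [(d, later, "g1") for d in (12, 15, 19, 22, 26)]
        return GrowthSeries(species_id=species, observations=obs)

    def test_max_of_species_minima(self):
        series = {
            "a": self._series("a", [0.010, 0.012]),
            "b": self._series("b", [0.0421, 0.050]),
            "c": self._series("c", [0.030]),
        }
        assert common_size(series) == pytest.approx(42.1)

    def test_single_species_returns_own_minimum(self):
        series = {"a": self._series("a", [0.010, 0.012])}
        assert common_size(series) == pytest.approx(10.0)

    def test_planted_minimum_returned_for_synthetic_group(self, default_config):
        series, truth = yp.simulate_growth_series(default_config.noiseless())
        grasses = [sp for sp in series
                   if truth.growth_params.loc[sp, "family"] == "grass"]
        cs = common_size(series, species=grasses)
        expected = max(min(m for d, m, _ in series[sp].observations
                           if d == min(o[0] for o in series[sp].observations))
                       for sp in grasses) * 1000.0
        assert cs == pytest.approx(expected, rel=1e-12)

    def test_empty_group_is_error(self):
        with pytest.raises(GrowthFitError):
            common_size({}, species=["nope"])


class TestGrowthIO:
    def test_round_trip(self, tmp_path, default_config):
        series, _ = yp.simulate_growth_series(default_config)
        path = tmp_path / "g.csv"
        write_growth_table(series.values(), path)
        back = read_growth_table(path)
        assert set(back) == set(series)
        sp = "Hordeum_vulgare"
        np.testing.assert_allclose(back[sp].masses, series[sp].masses)
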