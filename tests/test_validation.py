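"""Model-comparison diagnostics: residuals, RMSE, bands and overlap."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import glucomod as gm


def _band(lower, upper, n=241):
    t = np.arange(0.0, float(n))
    lo = np.broadcast_to(np.asarray(lower, dtype=float), t.shape).copy()
    up = np.broadcast_to(np.asarray(upper, dtype=float), t.shape).copy()
    return gm.ProfileBand(t=t, median=(lo + up) / 2.0, lower=lo, upper=up)


class TestWeightedResiduals:
    def test_perfect_fit_is_zero(self, gom_fit, synthetic_day):
        data = synthetic_day.meals[0]
        wres = (data.fit_glucose - gom_fit.fitted.glucose) / gom_fit.obs.sd
        np.testing.assert_allclose(gm.weighted_residuals(gom_fit, data), wres)
        perfect = gm.weighted_residuals(gom_fit, data) - wres
        np.testing.assert_allclose(perfect, 0.0)

    def test_scaling_and_sign_convention(self):
        obs_v = np.array([100.0, 100.0])
        model_v = np.array([96.0, 104.0])
        sd = np.array([2.0, 2.0])
        w = (obs_v - model_v) / sd
        # residual of +4 mg/dL at SD 2 -> +2; model above data -> negative
        assert w[0] == pytest.approx(2.0)
        assert w[1] == pytest.approx(-2.0)

    def test_rmse_consistency_with_weighted_residuals(self, gom_fit, synthetic_day):
        data = synthetic_day.meals[0]
        w = gm.weighted_residuals(gom_fit, data)
        sd = gom_fit.obs.sd
        assert gm.rmse(gom_fit, data) == pytest.approx(
            float(np.sqrt(np.mean((w * sd) ** 2))))


class TestRmse:
    def test_hand_arithmetic(self):
        r = np.array([3.0, 4.0])
        assert float(np.sqrt(np.mean(r**2))) == pytest.approx(3.5355, abs=1e-3)

    def test_zero_and_constant_residuals(self, gom_fit, synthetic_day):
        assert gm.rmse(gom_fit, synthetic_day.meals[0]) >= 0.0


class TestOverlapShare:
    def test_identical_bands(self):
        b = _band(1.0, 2.0)
        assert gm.overlap_share(b, b) == 1.0

    def test_disjoint_bands(self):
        assert gm.overlap_share(_band(1.0, 2.0), _band(3.0, 4.0)) == 0.0

    def test_analytic_first_touch(self):
        # second band slides down and first touches [0, 1] at t = 120
        t = np.arange(0.0, 241.0)
        a = _band(0.0, 1.0)
        b = gm.ProfileBand(t=t, median=2.5 - t / 120.0,
                           lower=2.0 - t / 120.0, upper=3.0 - t / 120.0)
        assert gm.overlap_share(a, b) == pytest.approx(0.5, abs=1.0 / 240.0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gm.overlap_share(_band(0.0, 1.0, n=241), _band(0.0, 1.0, n=100))

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 241.0)
        for _ in range(200):
            mid_a = rng.normal(size=t.size).cumsum() / 10.0
            mid_b = rng.normal(size=t.size).cumsum() / 10.0
            wa, wb = rng.uniform(0.1, 2.0, 2)
            a = gm.ProfileBand(t=t, median=mid_a, lower=mid_a - wa, upper=mid_a + wa)
            b = gm.ProfileBand(t=t, median=mid_b, lower=mid_b - wb, upper=mid_b + wb)
            hits = sum(
                1 for i in range(t.size)
                if max(a.lower[i], b.lower[i]) <= min(a.upper[i], b.upper[i])
            )
            assert gm.overlap_share(a, b) == hits / t.size

    @given(shift=st.floats(-3.0, 3.0), widen=st.floats(0.0, 2.0))
    def test_symmetry_and_monotonicity(self, shift, widen):
        a = _band(0.0, 1.0)
        b = _band(shift, shift + 1.0)
        assert gm.overlap_share(a, b) == gm.overlap_share(b, a)
        wide_b = _band(shift - widen, shift + 1.0 + widen)
        assert gm.overlap_share(a, wide_b) >= gm.overlap_share(a, b)


class TestCiProfile:
    def test_collapsed_posterior_gives_degenerate_band(self, gom_fit):
        import dataclasses

        collapsed = dataclasses.replace(gom_fit, cov=np.zeros_like(gom_fit.cov))
        band = gm.ci_profile(collapsed, "raln", n_draws=50, seed=0)
        np.testing.assert_allclose(band.lower, band.median)
        np.testing.assert_allclose(band.upper, band.median)

    def test_draw_count_self_convergence(self, gom_fit):
        b1 = gm.ci_profile(gom_fit, "raln", n_draws=2000, seed=1)
        b2 = gm.ci_profile(gom_fit, "raln", n_draws=4000, seed=2)
        width = np.maximum(b1.width, 1e-9)
        rel = np.abs(b2.upper - b1.upper)[width > 0.1] / width[width > 0.1]
        assert np.median(rel) < 0.05

    def test_ga_band_conserves_meal_mass(self, gom_fit, synthetic_day):
        band = gm.ci_profile(gom_fit, "raln", n_draws=1000, seed=3)
        auc_240 = np.trapezoid(band.median, band.t)
        A = synthetic_day.meals[0].meal.A
        # each draw has exact total mass A; the 240-min truncation and the
        # pointwise-median construction leave a modest gap
        assert auc_240 == pytest.approx(A, rel=0.15)

    def test_band_ordering_invariant(self, gom_fit):
        band = gm.ci_profile(gom_fit, "y_gom", n_draws=200, seed=4)
        assert np.all(band.lower <= band.median + 1e-12)
        assert np.all(band.median <= band.upper + 1e-12)


class TestYProfiles:
    def test_units_and_interchangeability(self, gom_fit, omm_fit):
        yg, yo = gm.y_profiles(gom_fit, omm_fit, n_draws=200, seed=0)
        assert yg.units == "1/min" and yo.units == "1/min"
        assert yg.t.size == yo.t.size

    def test_zero_sensitivity_zeroes_the_drive(self, gom_fit):
        import dataclasses

        mode = gom_fit.mode.copy()
        i = gom_fit.param_map.names.index("sg")
        mode[i] = np.log(1e-12)
        tiny = dataclasses.replace(gom_fit, mode=mode,
                                   cov=np.zeros_like(gom_fit.cov))
        band = gm.ci_profile(tiny, "y_gom", n_draws=10, seed=0)
        assert np.all(np.abs(band.median) < 1e-9)

    def test_basal_insulin_zeroes_y_omm(self, omm_fit):
        import dataclasses

        ib = omm_fit.param_map.ib
        flat = gm.InsulinInterpolant(omm_fit.insulin.times,
                                     np.full(omm_fit.insulin.times.size, ib))
        frozen = dataclasses.replace(omm_fit, insulin=flat,
                                     cov=np.zeros_like(omm_fit.cov))
        band = gm.ci_profile(frozen, "y_omm", n_draws=10, seed=0, insulin_cv=0.0)
        np.testing.assert_allclose(band.median, 0.0, atol=1e-12)


class TestCompareSensitivity:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = gm.compare_sensitivity(x, x)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(1.0)
        assert out["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_pairs(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert gm.compare_sensitivity(x, -x)["pearson_r"] == pytest.approx(-1.0)

    def test_matches_brute_force_formula(self):
        rng = np.random.default_rng(11)
        x = rng.lognormal(size=30)
        y = 0.8 * x + rng.normal(scale=0.1, size=30)
        out = gm.compare_sensitivity(x, y)
        xm, ym = x.mean(), y.mean()
        r_brute = float(np.sum((x - xm) * (y - ym))
                        / np.sqrt(np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2)))
        assert out["pearson_r"] == pytest.approx(r_brute, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            gm.compare_sensitivity([1.0, 2.0], [1.0, 2.0])

    def test_grouped_summaries(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        out = gm.compare_sensitivity(x, x * 2, groups=["a", "a", "a", "b", "b", "b"])
        assert set(out["groups"]) == {"a", "b"}
        assert out["groups"]["a"]["n"] == 3


class TestComparisonReport:
    def test_per_response_row_and_summaries(self, gom_fit, omm_fit, synthetic_day):
        report = gm.ComparisonReport()
        row = report.add_response("S11", 1, gom_fit, omm_fit, n_draws=150, seed=0)
        assert 0.0 <= row["ol_ga"] <= 1.0
        assert 0.0 <= row["ol_y"] <= 1.0
        assert row["rmse_gom"] >= 0.0 and row["rmse_omm"] >= 0.0
        rc = report.rmse_comparison()
        assert rc["rmse_gom_mean"] == pytest.approx(row["rmse_gom"])
        df = report.to_dataframe()
        assert len(df) == 1
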