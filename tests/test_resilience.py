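"""Resilience quantification: hand-computed distances, tipping calibration
invariants, attractor extension, and landscape interpolation identities."""

import numpy as np
import pandas as pd
import pytest

from ecoira.resilience import (Attractor, ResilienceAssessment, build_attractors,
                               compute_resilience, stability_landscape,
                               standardize_axes)
from ecoira.smoothing import fit_penalized_spline
from ecoira.threshold_models import ThresholdGAM, build_lagged_frame


class LinearAttractor(Attractor):
    """Closed-form attractor for hand examples."""

    def __init__(self, intercept, slope, x_min=-10, x_max=10, regime=0):
        fit = fit_penalized_spline(np.linspace(x_min, x_max, 8),
                                   intercept + slope * np.linspace(x_min, x_max, 8),
                                   lam=np.inf)
        super().__init__(fit, x_min, x_max, regime)


def two_regime_inputs(x0, z0, reg, years=None):
    years = years if years is not None else 2000 + np.arange(len(x0))
    idx = pd.Index(years, name="year")
    return (pd.Series(x0, index=idx), pd.Series(z0, index=idx),
            pd.Series(reg, index=idx))


class TestStandardizeAxes:
    def test_means_zero_sds_one(self):
        rng = np.random.default_rng(71)
        idx = pd.Index(np.arange(2000, 2026))
        z = pd.Series(rng.normal(3, 2, 26), index=idx)
        x = pd.Series(rng.normal(-1, 0.5, 26), index=idx)
        zs, xs = standardize_axes(z, x)
        for s in (zs, xs):
            assert s.mean() == pytest.approx(0.0, abs=1e-12)
            assert s.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_and_invertible(self):
        rng = np.random.default_rng(72)
        idx = pd.Index(np.arange(2000, 2026))
        z = pd.Series(rng.normal(3, 2, 26), index=idx)
        x = pd.Series(rng.normal(0, 1, 26), index=idx)
        zs, xs = standardize_axes(z, x)
        zs2, xs2 = standardize_axes(zs, xs)
        pd.testing.assert_series_equal(zs, zs2, atol=1e-12)
        recovered = zs * z.std(ddof=1) + z.mean()
        np.testing.assert_allclose(recovered, z, atol=1e-12)

    def test_constant_series_rejected(self):
        idx = pd.Index(np.arange(2000, 2026))
        with pytest.raises(ValueError):
            standardize_axes(pd.Series(1.0, index=idx),
                             pd.Series(np.arange(26.0), index=idx))


class TestAttractors:
    @pytest.fixture()
    def tgam_fit(self):
        rng = np.random.default_rng(73)
        years = np.arange(1994, 2020)
        x = rng.normal(0, 1, 26)
        y = 0.8 * x + np.where(years >= 2007, -1.5, 1.5) + rng.normal(0, 0.2, 26)
        f = build_lagged_frame(pd.Series(y, index=years), pd.Series(x, index=years), 0)
        return ThresholdGAM(f).fit()

    def test_attractor_equals_branch_at_observed_stressors(self, tgam_fit):
        att = build_attractors(tgam_fit)
        f = tgam_fit.frame
        for r in (0, 1):
            m = tgam_fit.regime_of(f.years) == r
            np.testing.assert_allclose(att[r](f.stressor[m]),
                                       tgam_fit.branches[r].predict(f.stressor[m]),
                                       atol=1e-10)

    def test_extension_continues_with_boundary_derivative(self, tgam_fit):
        att = build_attractors(tgam_fit)[0]
        x_hi = att.x_max
        eps = 1e-5
        slope_fd = (att(np.array([x_hi + eps]))[0] - att(np.array([x_hi - eps]))[0]) / (2 * eps)
        for dx in (0.5, 1.7):
            expected = att(np.array([x_hi]))[0] + slope_fd * dx
            assert att(np.array([x_hi + dx]))[0] == pytest.approx(expected, rel=1e-4)

    def test_linear_branch_extends_to_global_line(self):
        att = LinearAttractor(0.5, -1.2, x_min=-1, x_max=1)
        xs = np.array([-5.0, -1.0, 0.3, 4.0])
        np.testing.assert_allclose(att(xs), 0.5 - 1.2 * xs, atol=1e-8)

    def test_gam_input_rejected(self):
        from ecoira.threshold_models import GAM
        rng = np.random.default_rng(74)
        years = np.arange(1994, 2020)
        f = build_lagged_frame(pd.Series(rng.normal(0, 1, 26), index=years),
                               pd.Series(rng.normal(0, 1, 26), index=years), 0)
        with pytest.raises(TypeError):
            build_attractors(GAM(f).fit())


class TestComputeResilience:
    def test_hand_example_on_attractor(self):
        # three on-attractor years at x = -1, 0, 1; tipping side low_x
        x, z, reg = two_regime_inputs([-1.0, 0.0, 1.0, 0.2, 0.4],
                                      [0.0, 0.0, 0.0, -2.0, -2.0],
                                      [0, 0, 0, 1, 1])
        atts = {0: LinearAttractor(0.0, 0.0), 1: LinearAttractor(-2.0, 0.0, regime=1)}
        res = compute_resilience(x, z, reg, atts,
                                 tipping_sides={0: "low_x", 1: "low_x"})
        np.testing.assert_allclose(res.per_year["res"].iloc[:3], [0.0, 1.0, 2.0],
                                   atol=1e-12)
        assert res.tipping_points[0] == pytest.approx(-1.0)
        # global max Res is 2 -> rRes of regime-0 years = (0, 0.5, 1)
        np.testing.assert_allclose(res.per_year["rres"].iloc[:3], [0.0, 0.5, 1.0],
                                   atol=1e-12)

    def test_on_attractor_res_equals_horizontal_distance(self):
        rng = np.random.default_rng(75)
        xv = np.concatenate([rng.uniform(-1, 1, 6), rng.uniform(-1, 1, 6)])
        reg = np.array([0] * 6 + [1] * 6)
        zv = np.where(reg == 0, 1.0 + 0.5 * xv, -1.0 + 0.5 * xv)  # exactly on lines
        x, z, r = two_regime_inputs(xv, zv, reg)
        atts = {0: LinearAttractor(1.0, 0.5), 1: LinearAttractor(-1.0, 0.5, regime=1)}
        res = compute_resilience(x, z, r, atts)
        np.testing.assert_allclose(res.per_year["res"], res.per_year["h"], atol=1e-10)
        # noiseless case: every Res equals its analytic value |x - x_F|
        for i, (xx, rr) in enumerate(zip(xv, reg)):
            assert res.per_year["res"].iloc[i] == pytest.approx(
                abs(xx - res.tipping_points[rr]), abs=1e-10)

    def test_min_res_zero_per_regime_and_max_rres_one(self, fitted_resilience):
        per = fitted_resilience.per_year.dropna(subset=["res"])
        for r in (0, 1):
            assert per.loc[per["regime"] == r, "res"].min() == pytest.approx(0.0, abs=1e-12)
        assert per["rres"].max() == pytest.approx(1.0, abs=1e-12)
        assert (per["rres"] >= 0).all()

    def test_excluded_years_carry_no_value_and_do_not_calibrate(self):
        x, z, reg = two_regime_inputs([-1.0, 0.0, 1.0, 3.0, 0.2, 0.4],
                                      [0.0, 0.0, 0.0, 0.0, -2.0, -2.0],
                                      [0, 0, 0, 0, 1, 1])
        atts = {0: LinearAttractor(0.0, 0.0), 1: LinearAttractor(-2.0, 0.0, regime=1)}
        full = compute_resilience(x, z, reg, atts,
                                  tipping_sides={0: "low_x", 1: "low_x"})
        # excluding the x=3 year removes it from the rRes maximum
        excl = compute_resilience(x, z, reg, atts,
                                  tipping_sides={0: "low_x", 1: "low_x"},
                                  excluded_years=[2003])
        assert np.isnan(excl.per_year.loc[2003, "res"])
        assert full.per_year["res"].max() == pytest.approx(4.0)
        assert excl.per_year.drop(2003)["rres"].max() == pytest.approx(1.0)
        assert excl.per_year.loc[2002, "rres"] > full.per_year.loc[2002, "rres"]

    def test_res_invariant_to_year_order_within_regime(self):
        xv = [-1.0, 0.0, 1.0, 0.2, 0.4, 0.9]
        zv = [0.1, -0.1, 0.0, -2.1, -1.9, -2.0]
        reg = [0, 0, 0, 1, 1, 1]
        atts = {0: LinearAttractor(0.0, 0.0), 1: LinearAttractor(-2.0, 0.0, regime=1)}
        x1, z1, r1 = two_regime_inputs(xv, zv, reg)
        res1 = compute_resilience(x1, z1, r1, atts, {0: "low_x", 1: "low_x"})
        perm = [2, 0, 1, 5, 3, 4]  # permute years within each regime
        x2, z2, r2 = two_regime_inputs([xv[i] for i in perm], [zv[i] for i in perm],
                                       [reg[i] for i in perm])
        res2 = compute_resilience(x2, z2, r2, atts, {0: "low_x", 1: "low_x"})
        got = dict(zip(x2.to_numpy(), res2.per_year["res"]))
        for xx, rr in zip(x1.to_numpy(), res1.per_year["res"]):
            assert got[xx] == pytest.approx(rr, abs=1e-12)

    def test_single_regime_rejected(self):
        x, z, reg = two_regime_inputs([0.0, 1.0, 2.0], [0.0, 0.0, 0.0], [0, 0, 0])
        with pytest.raises(ValueError):
            compute_resilience(x, z, reg, {0: LinearAttractor(0, 0)}, {0: "low_x"})


@pytest.fixture(scope="module")
def fitted_resilience(request):
    """Resilience of the default synthetic fixture's optimal TGAM."""
    from ecoira.ordination import filter_species, run_pca
    from ecoira.synthetic import simulate_dataset
    ds = simulate_dataset(seed=1)
    pca = run_pca(filter_species(ds.biomass, 21))
    f = build_lagged_frame(pca.scores["PC1"], ds.stressors[("chl", "winter")],
                           ds.truth.lag)
    tg = ThresholdGAM(f).fit()
    return ResilienceAssessment(tg).fit()


class TestStabilityLandscape:
    def test_grid_shape_and_hull_bounds(self, fitted_resilience):
        grid = fitted_resilience.landscape
        assert grid.shape == (100, 100)
        inside = grid[~np.isnan(grid)]
        assert inside.size > 0
        assert inside.min() >= -1e-9 and inside.max() <= 1.0 + 1e-9

    def test_interpolant_exact_at_data_points(self, fitted_resilience):
        r = fitted_resilience
        py = r.per_year.dropna(subset=["rres"])
        from scipy.interpolate import griddata
        vals = griddata(py[["x", "z"]].to_numpy(), py["rres"].to_numpy(),
                        py[["x", "z"]].to_numpy(), method="linear")
        np.testing.assert_allclose(vals, py["rres"], atol=1e-6)
        # nearest grid cell approximates each observation
        for _, row in py.iloc[::5].iterrows():
            i = np.argmin(np.abs(r.landscape_x - row["x"]))
            j = np.argmin(np.abs(r.landscape_z - row["z"]))
            if not np.isnan(r.landscape[j, i]):
                assert r.landscape[j, i] == pytest.approx(row["rres"], abs=0.15)

    def test_triangle_centroid_is_barycentric_mean(self):
        x, z, reg = two_regime_inputs([0.0, 1.0, 0.5, 0.2, 0.8],
                                      [0.0, 0.0, 1.0, 0.2, 0.2],
                                      [0, 0, 0, 1, 1])
        atts = {0: LinearAttractor(0.0, 0.0), 1: LinearAttractor(0.2, 0.0, regime=1)}
        res = compute_resilience(x, z, reg, atts, {0: "low_x", 1: "low_x"})
        res.per_year = res.per_year.iloc[:3].copy()  # keep an exact triangle
        res.per_year.loc[:, "rres"] = [0.0, 0.5, 1.0]
        grid, gx, gz = stability_landscape(res)
        cx, cz = np.mean([0.0, 1.0, 0.5]), np.mean([0.0, 0.0, 1.0])
        i, j = np.argmin(np.abs(gx - cx)), np.argmin(np.abs(gz - cz))
        assert grid[j, i] == pytest.approx(0.5, abs=0.02)

    def test_linearity_in_rres_values(self, fitted_resilience):
        r = fitted_resilience
        doubled = r.per_year.copy()
        doubled["rres"] = 2.0 * doubled["rres"]
        from ecoira.resilience import ResilienceResult
        r2 = ResilienceResult(per_year=doubled, tipping_points=r.tipping_points,
                              tipping_sides=r.tipping_sides, attractors=r.attractors,
                              excluded_years=[])
        grid2, _, _ = stability_landscape(r2)
        mask = ~np.isnan(r.landscape)
        np.testing.assert_allclose(grid2[mask], 2.0 * r.landscape[mask], atol=1e-9)

    def test_collinear_points_rejected(self):
        x, z, reg = two_regime_inputs([0.0, 1.0, 2.0, 3.0],
                                      [0.0, 1.0, 2.0, 3.0], [0, 0, 1, 1])
        atts = {0: LinearAttractor(0.0, 1.0), 1: LinearAttractor(0.0, 1.0, regime=1)}
        res = compute_resilience(x, z, reg, atts, {0: "low_x", 1: "low_x"})
        with pytest.raises(ValueError, match="collinear|degenerate"):
            stability_landscape(res)
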