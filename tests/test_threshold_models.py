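"""GAM/TGAM contracts: lagged pairing, exact fits, genuine cross-validation
against an explicit leave-one-out oracle, grid enumeration and selection."""

import numpy as np
import pandas as pd
import pytest

from ecoira.smoothing import fit_penalized_spline
from ecoira.threshold_models import (GAM, LAGS, SEASONS, STRESSOR_VARS, LaggedFrame,
                                     ThresholdGAM, build_lagged_frame,
                                     enumerate_model_grid, genuine_cv,
                                     select_best_model, threshold_candidates,
                                     _fit_for_spec)

YEARS = np.arange(1994, 2020)


def make_frame(response, stressor, lag=0, years=YEARS):
    return build_lagged_frame(pd.Series(response, index=years),
                              pd.Series(stressor, index=years - lag), lag)


def loo_oracle(frame, model_type, k=4, min_branch_years=5):
    """Independent explicit leave-one-out loop (no caching, no shortcuts)."""
    errs = []
    for i in range(frame.n):
        sub = frame.drop(i)
        try:
            res = _fit_for_spec(sub, model_type, k, min_branch_years)
        except ValueError:
            res = GAM(sub, k=k).fit()
        pred = res.predict(frame.stressor[i:i + 1], frame.years[i:i + 1])[0]
        errs.append((frame.response[i] - pred) ** 2)
    return float(np.mean(errs))


class TestBuildLaggedFrame:
    def test_zero_lag_keeps_all_years(self):
        rng = np.random.default_rng(51)
        f = make_frame(rng.normal(0, 1, 26), rng.normal(0, 1, 26), lag=0)
        assert f.n == 26

    def test_two_year_lag_pairing(self):
        rng = np.random.default_rng(52)
        resp = pd.Series(rng.normal(0, 1, 26), index=YEARS)
        stress = pd.Series(np.arange(26, dtype=float), index=YEARS)  # value = year-1994
        f = build_lagged_frame(resp, stress, lag=2)
        assert f.n == 24
        assert f.years[0] == 1996
        assert f.stressor[0] == 0.0  # the 1994 stressor value

    def test_pairing_matches_join_oracle(self):
        rng = np.random.default_rng(53)
        resp = pd.Series(rng.normal(0, 1, 26), index=YEARS)
        stress = pd.Series(rng.normal(0, 1, 28), index=np.arange(1992, 2020))
        f = build_lagged_frame(resp, stress, lag=1, standardize_response=False)
        joined = {y: (resp[y], stress[y - 1]) for y in YEARS if (y - 1) in stress.index}
        assert f.n == len(joined)
        for yr, r, s in zip(f.years, f.response, f.stressor):
            assert (r, s) == joined[yr]

    def test_response_standardized_over_retained_years(self):
        rng = np.random.default_rng(54)
        f = make_frame(5 + 3 * rng.normal(0, 1, 26), rng.normal(0, 1, 26))
        assert f.response.mean() == pytest.approx(0.0, abs=1e-12)
        assert f.response.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_insufficient_stressor_coverage(self):
        resp = pd.Series(np.arange(26.0), index=YEARS)
        stress = pd.Series([1.0], index=[1800])
        with pytest.raises(ValueError):
            build_lagged_frame(resp, stress, lag=0)


class TestGAM:
    def test_noiseless_linear_fit_is_exact(self):
        rng = np.random.default_rng(55)
        x = rng.normal(0, 1, 26)
        f = make_frame(0.7 * x + 0.1, x)
        res = GAM(f).fit()
        assert res.variance_explained == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(res.fittedvalues, f.response, atol=1e-6)

    def test_infinite_penalty_reduces_to_ols_line(self):
        rng = np.random.default_rng(56)
        x = rng.normal(0, 1, 26)
        f = make_frame(0.5 * x + rng.normal(0, 0.5, 26), x)
        res = GAM(f).fit(lam=np.inf)
        X = np.column_stack([np.ones(f.n), f.stressor])
        beta = np.linalg.lstsq(X, f.response, rcond=None)[0]
        np.testing.assert_allclose(res.fittedvalues, X @ beta, atol=1e-6)

    def test_constant_stressor_raises(self):
        with pytest.raises(ValueError):
            GAM(make_frame(np.arange(26.0), np.ones(26)))

    def test_too_few_pairs_raise(self):
        f = LaggedFrame(YEARS[:5], np.arange(5.0), np.arange(5.0), 0)
        with pytest.raises(ValueError):
            GAM(f)


class TestGenuineCV:
    def test_matches_explicit_loo_loop(self, default_dataset, default_pca):
        f = build_lagged_frame(default_pca.scores["PC1"],
                               default_dataset.stressors[("chl", "winter")], 1)
        for mt in ("GAM", "TGAM"):
            assert genuine_cv(f, mt) == pytest.approx(loo_oracle(f, mt), abs=1e-10)

    def test_interpolating_noiseless_model_has_zero_gcv(self):
        rng = np.random.default_rng(57)
        x = rng.normal(0, 1, 26)
        f = make_frame(1.3 * x, x)
        assert genuine_cv(f, "GAM") == pytest.approx(0.0, abs=1e-10)

    def test_null_model_reference_on_standardized_response(self):
        # LOO of the intercept-only model on unit-variance response:
        # exactly (n/(n-1))^2 * mean residual^2 = n^2/(n-1)^2 * (n-1)/n = n/(n-1)
        rng = np.random.default_rng(58)
        f = make_frame(rng.normal(0, 1, 26), rng.normal(0, 1, 26))
        y = f.response
        n = f.n
        loo_null = np.mean([(y[i] - np.delete(y, i).mean()) ** 2 for i in range(n)])
        assert loo_null == pytest.approx(n / (n - 1), abs=1e-10)
        # fitted models on pure-noise pairs should not be far above it
        assert genuine_cv(f, "GAM") < 2.0 * loo_null


class TestThresholdGAM:
    def test_recovers_threshold_on_offset_parallel_lines(self):
        rng = np.random.default_rng(59)
        noise_sd = 0.2
        x = rng.normal(0, 1, 26)
        y = 0.6 * x + np.where(YEARS >= 2007, -5 * noise_sd, 5 * noise_sd)
        y = y + rng.normal(0, noise_sd, 26)
        res = ThresholdGAM(make_frame(y, x)).fit()
        assert res.threshold_year == 2007

    def test_branches_partition_years_with_min_size(self, default_dataset, default_pca):
        f = build_lagged_frame(default_pca.scores["PC1"],
                               default_dataset.stressors[("chl", "winter")], 1)
        res = ThresholdGAM(f, min_branch_years=5).fit()
        pre = (f.years < res.threshold_year).sum()
        assert pre >= 5 and f.n - pre >= 5

    def test_equal_branches_reproduce_gam(self):
        # fitting the branch smoother to the full data twice must equal the
        # single-smooth GAM: the branch estimator IS the GAM estimator
        rng = np.random.default_rng(60)
        x = rng.normal(0, 1, 26)
        f = make_frame(np.sin(x) + rng.normal(0, 0.3, 26), x)
        gam = GAM(f).fit()
        branch = fit_penalized_spline(f.stressor, f.response, k=4)
        np.testing.assert_allclose(branch.fitted, gam.fittedvalues, atol=1e-8)

    def test_restricted_candidate_grid_flagged(self):
        rng = np.random.default_rng(61)
        x = rng.normal(0, 1, 26)
        y = 0.6 * x + np.where(YEARS >= 2007, -2.0, 2.0) + rng.normal(0, 0.2, 26)
        model = ThresholdGAM(make_frame(y, x), candidates=[2003, 2012, 1990])
        res = model.fit()
        assert res.threshold_year in (2003, 2012)
        assert res.candidates_restricted  # 1990 infeasible -> flagged

    def test_no_feasible_candidates_raises(self):
        rng = np.random.default_rng(62)
        f = make_frame(rng.normal(0, 1, 26), rng.normal(0, 1, 26))
        with pytest.raises(ValueError):
            ThresholdGAM(f, candidates=[1901])

    def test_candidates_respect_branch_minimum(self):
        cands = threshold_candidates(YEARS, 5)
        assert cands[0] == YEARS[5] and cands[-1] == YEARS[-5]

    def test_single_regime_data_prefers_gam_on_gcv(self):
        rng = np.random.default_rng(63)
        worse = 0
        n_rep = 200
        for _ in range(n_rep):
            x = rng.normal(0, 1, 26)
            y = 0.8 * x + rng.normal(0, 0.5, 26)
            f = make_frame(y, x)
            worse += genuine_cv(f, "TGAM") >= genuine_cv(f, "GAM")
        assert worse / n_rep >= 0.80


class TestModelSelection:
    def test_grid_enumerates_18_plus_18_models(self):
        grid = enumerate_model_grid()
        assert len(grid) == 36
        assert sum(c["model_type"] == "GAM" for c in grid) == 18
        assert sum(c["model_type"] == "TGAM" for c in grid) == 18
        combos = {(c["stressor"], c["season"], c["lag"]) for c in grid}
        assert len(combos) == len(STRESSOR_VARS) * len(SEASONS) * len(LAGS)

    def test_missing_stressor_cells_marked_absent(self, default_pca, default_dataset):
        stressors = {("chl", "winter"): default_dataset.stressors[("chl", "winter")]}
        sel = select_best_model({"PC1": default_pca.scores["PC1"]}, stressors,
                                lags=(0, 1))
        absent = sel.table[sel.table["status"] == "absent"]
        assert len(absent) == (6 - 1) * 2 * 2  # 5 missing combos x 2 lags x 2 types
        assert sel.best_row()["stressor"] == "chl"

    def test_tie_break_prefers_gam_then_smaller_lag(self):
        table = pd.DataFrame([
            {"response": "PC1", "stressor": "chl", "season": "winter", "lag": 2,
             "model_type": "TGAM", "gcv": 0.5, "variance_explained": 0.9,
             "threshold_year": 2005, "status": "ok"},
            {"response": "PC1", "stressor": "chl", "season": "winter", "lag": 1,
             "model_type": "GAM", "gcv": 0.5 + 1e-14, "variance_explained": 0.5,
             "threshold_year": None, "status": "ok"},
            {"response": "PC1", "stressor": "sst", "season": "winter", "lag": 0,
             "model_type": "GAM", "gcv": 0.5 + 2e-14, "variance_explained": 0.5,
             "threshold_year": None, "status": "ok"},
        ])
        from ecoira.threshold_models import ModelSelection
        best = ModelSelection(table=table).best_row()
        assert best["model_type"] == "GAM" and best["lag"] == 0

    def test_true_cell_recovered_across_replicates(self):
        # full grid with genuine CV on the default fixture; truth is a TGAM
        # on winter chlorophyll at the truth's lag
        from ecoira.ordination import filter_species, run_pca
        from ecoira.synthetic import simulate_dataset
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            ds = simulate_dataset(seed=seed)
            pca = run_pca(filter_species(ds.biomass, 21))
            sel = select_best_model({"PC1": pca.scores["PC1"]}, ds.stressors)
            r = sel.best_row()
            hits += (r["model_type"] == "TGAM" and r["stressor"] == "chl"
                     and r["season"] == "winter" and r["lag"] == ds.truth.lag)
        assert hits / n_rep >= 0.90
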