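"""Linear yield models, the correlation screen and LOOCV."""

import numpy as np
import pandas as pd
import pytest

from stageyield import (WeightedStageYieldRegressor, WeightVector,
                        correlation_screen, fit_linear, loocv, predict_yield,
                        weighted_composite)
from stageyield.errors import ValidationError
from stageyield.growth import STAGES
from stageyield.regression import stage_matrix


class TestFitLinear:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.p_value == 0.0

    def test_orthogonal_fixture(self):
        # sample correlation exactly zero by construction
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])
        fit = fit_linear(x, y)
        assert fit.slope == pytest.approx(0.0, abs=1e-15)
        assert fit.f_stat == pytest.approx(0.0, abs=1e-28)

    def test_against_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            fit = fit_linear(x, y)
            res = sm.OLS(y, sm.add_constant(x)).fit()
            assert fit.intercept == pytest.approx(res.params[0], abs=1e-10)
            assert fit.slope == pytest.approx(res.params[1], abs=1e-10)
            assert fit.r2 == pytest.approx(res.rsquared, abs=1e-10)
            assert fit.f_stat == pytest.approx(res.fvalue, rel=1e-8)
            assert fit.p_value == pytest.approx(res.f_pvalue, rel=1e-8)

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            fit_linear([1.0, 2.0], [1.0, 2.0])


class TestLoocv:
    def test_perfect_line(self):
        x = np.arange(8.0)
        cv = loocv(x, 3 * x - 2, ref_yield=10.0)
        assert cv.rmse_cv == pytest.approx(0.0, abs=1e-10)
        assert cv.mre == pytest.approx(0.0, abs=1e-12)
        assert cv.coef_mean[0] == pytest.approx(3.0)
        assert cv.coef_mean[1] == pytest.approx(-2.0)
        assert cv.K == 8

    def test_hat_matrix_shortcut(self):
        rng = np.random.default_rng(22)
        x = rng.normal(size=20)
        y = 0.8 * x + rng.normal(size=20) * 0.3
        cv = loocv(x, y, ref_yield=5.0)
        X = np.column_stack([np.ones(20), x])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        e = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        shortcut = y - e / (1 - np.diag(H))
        assert np.abs(cv.predictions - shortcut).max() < 1e-10

    def test_cv_rmse_at_least_fit_rmse(self):
        """LOOCV error is never optimistic relative to the training fit."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            fit = fit_linear(x, y)
            cv = loocv(x, y, ref_yield=100.0)
            assert cv.rmse_cv >= fit.rmse - 1e-12


class TestComposite:
    def test_one_hot_returns_single_stage(self, toy_obs):
        w = WeightVector(np.eye(5)[2], "one-hot")  # TES
        comp = weighted_composite(toy_obs, w, "lai")
        tes = stage_matrix(toy_obs, "lai")["TES"]
        assert np.allclose(comp, tes)

    def test_uniform_weights_average(self, toy_obs):
        w = WeightVector(np.full(5, 0.2), "uniform")
        comp = weighted_composite(toy_obs, w, "lai")
        assert np.allclose(comp, stage_matrix(toy_obs, "lai").mean(axis=1))

    def test_hand_dot_product(self):
        rows = [{"plot_id": "p", "stage": s, "v": v}
                for s, v in zip(STAGES, (1.0, 1.0, 2.0, 1.0, 1.0))]
        obs = pd.DataFrame(rows)
        w = WeightVector(np.array([0.1, 0.2, 0.4, 0.2, 0.1]), "w")
        assert weighted_composite(obs, w, "v").iloc[0] == pytest.approx(1.4)


class TestPredictYield:
    def test_intercept_at_zero(self):
        fit = fit_linear(np.arange(5.0), 2 * np.arange(5.0) + 1)
        assert predict_yield(fit, 0.0, ref_yield=7.0) == pytest.approx(8.0)

    def test_weighted_model_coefficients(self):
        """Structure slope*x + intercept + ref_yield with published
        weighted-stage coefficients."""
        from stageyield.regression import RegressionFit

        fit = RegressionFit(slope=0.5169, intercept=-0.2330, r2=0.84, adj_r2=0.8333,
                            rmse=0.2187, f_stat=100.0, p_value=1e-9, n=26)
        assert predict_yield(fit, 1.0, ref_yield=10.0) == pytest.approx(10.2839)

    def test_reference_plot_prediction_near_its_yield(self, default_trial):
        from stageyield import relativize_table, select_reference

        plots, obs = default_trial.plots, default_trial.observations
        ref = select_reference(plots)
        rel, rel_yield = relativize_table(obs, plots, ref)
        wide = stage_matrix(rel, "lai")
        fit = fit_linear(wide["TES"], rel_yield.loc[wide.index])
        ref_yield = float(plots.set_index("plot_id").loc[ref, "yield_kg"])
        pred = predict_yield(fit, wide.loc[ref, "TES"], ref_yield)
        assert pred == pytest.approx(ref_yield + fit.intercept)


class TestCorrelationScreen:
    def test_exact_linear_relation(self, toy_plots):
        rng = np.random.default_rng(30)
        y = pd.Series([1.0, 3.0, 2.0], index=["p1", "p2", "p3"], name="relative_yield")
        rows = [{"plot_id": p, "stage": s, "v": 2 * y[p] + rng.normal() * 0}
                for p in y.index for s in STAGES]
        screen = correlation_screen(pd.DataFrame(rows), y)
        assert np.allclose(screen["r"].to_numpy(dtype=float), 1.0)

    def test_negation_flips_sign(self, toy_obs):
        y = pd.Series([1.0, 3.0, 2.0], index=["p1", "p2", "p3"])
        r1 = correlation_screen(toy_obs, y)["r"]
        neg = toy_obs.assign(lai=-toy_obs["lai"])
        r2 = correlation_screen(neg, y)["r"]
        assert np.allclose(r2["lai"].to_numpy(dtype=float),
                           -r1["lai"].to_numpy(dtype=float))

    def test_zero_variance_reported_missing(self, toy_obs):
        flat = toy_obs.assign(lai=1.0)
        y = pd.Series([1.0, 3.0, 2.0], index=["p1", "p2", "p3"])
        assert correlation_screen(flat, y)["r"]["lai"].isna().all()

    def test_default_trial_peaks_mid_season(self, default_trial):
        """Yield is coupled to mid-season canopy state, so per-index maxima
        should sit at TES or SAS for nearly all indices."""
        from stageyield import relativize_table, select_reference

        plots, obs = default_trial.plots, default_trial.observations
        ref = select_reference(plots)
        rel, rel_yield = relativize_table(obs, plots, ref)
        rel = rel[rel["plot_id"] != ref]
        screen = correlation_screen(rel, rel_yield.drop(ref))
        indices = ["NDVI", "CIrededge", "CIgreen", "EVI2", "NDRE", "MTCI"]
        best = screen["best_stage"][indices]
        assert (best.isin(["TES", "SAS"])).sum() >= 5


class TestWeightedStageYieldRegressor:
    def _xy(self, trial):
        from stageyield import relativize_table, select_reference

        plots, obs = trial.plots, trial.observations
        ref = select_reference(plots)
        rel, rel_yield = relativize_table(obs, plots, ref)
        rel = rel[rel["plot_id"] != ref]
        X = stage_matrix(rel, "lai")
        return X, rel_yield.loc[X.index], float(
            plots.set_index("plot_id").loc[ref, "yield_kg"])

    def test_fit_predict_and_params(self, default_trial):
        X, y, ref_yield = self._xy(default_trial)
        est = WeightedStageYieldRegressor(weighting="ocw", alpha=0.7, ref_yield=ref_yield)
        assert est.get_params()["alpha"] == 0.7
        est.fit(X, y)
        assert est.stage_weights_.w.sum() == pytest.approx(1.0)
        assert 0.0 < est.adj_r2_ <= 1.0
        pred_rel = est.predict(X)
        assert np.allclose(est.predict_absolute(X), pred_rel + ref_yield)
        # score is R^2 of the composite model
        assert est.score(X, y) == pytest.approx(est.fit_.r2, abs=1e-9)

    def test_explicit_weights_match_manual_composite(self, default_trial):
        X, y, _ = self._xy(default_trial)
        w = np.array([0.05, 0.15, 0.45, 0.25, 0.10])
        est = WeightedStageYieldRegressor(weighting=w).fit(X, y)
        manual = fit_linear(X.to_numpy() @ w, y.to_numpy())
        assert est.slope_ == pytest.approx(manual.slope)
        assert est.adj_r2_ == pytest.approx(manual.adj_r2)

    def test_loocv_method(self, default_trial):
        X, y, ref_yield = self._xy(default_trial)
        est = WeightedStageYieldRegressor(ref_yield=ref_yield).fit(X, y)
        cv = est.loocv(X, y)
        assert cv.K == len(X)
        assert cv.rmse_cv >= est.rmse_ - 1e-12

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = WeightedStageYieldRegressor(weighting="iahp", alpha=0.55)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
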