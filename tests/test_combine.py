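import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from emeq.combine import (
    CollinearityError,
    CombinedEquationModel,
    ZeroVarianceError,
    back_transform,
    candidate_models,
    fit_all_candidates,
    fit_mixed,
    screen_collinearity,
    select_model,
    standardize,
    vif,
)
from emeq.diets import diets_to_frame
from emeq.synth import SimulationParams, simulate_predictions


class TestStandardize:
    def test_simple_column(self):
        df = pd.DataFrame({"NDF": [1.0, 2.0, 3.0]})
        X, scaling = standardize(df, ["NDF"])
        assert scaling.means["NDF"] == 2.0 and scaling.sds["NDF"] == 1.0
        assert np.allclose(X["NDF"], [-1.0, 0.0, 1.0])

    def test_columns_have_zero_mean_unit_sd(self, preds):
        X, _ = standardize(preds, ["ME", "NDF", "EE"])
        assert np.allclose(X.mean(), 0.0, atol=1e-10)
        assert np.allclose(X.std(ddof=1), 1.0, atol=1e-10)

    def test_stacked_column_sd_scales_by_repeated_row_correction(self, preds):
        # the 15 diet values repeated 32 times: SD over 480 rows equals the
        # 15-diet sum of squares rescaled to the 479 denominator
        _, scaling = standardize(preds, ["NDF"])
        per_diet = preds.frame.drop_duplicates("diet_id")["ndf_pct"]
        ss15 = ((per_diet - per_diet.mean()) ** 2).sum()
        assert scaling.sds["NDF"] == pytest.approx(np.sqrt(ss15 * 32 / 479))

    def test_invert_round_trip(self, preds):
        X, scaling = standardize(preds, ["ME", "NDF"])
        raw = scaling.invert(X)
        assert np.allclose(raw["NDF"], preds.frame["ndf_pct"], atol=1e-10)

    def test_zero_variance_predictor_named(self, preds):
        with pytest.raises(ZeroVarianceError, match="ASH"):
            standardize(preds, ["ASH"])  # ash is a single default value

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=30, unique=True))
    def test_round_trip_property(self, values):
        df = pd.DataFrame({"NDF": values})
        X, scaling = standardize(df, ["NDF"])
        assert np.allclose(scaling.invert(X)["NDF"], values, rtol=1e-9, atol=1e-7)


class TestScreenCollinearity:
    def test_fixture_fibre_pair_grouped(self, completed):
        res = screen_collinearity(completed)
        assert round(res.correlations.loc["NDF", "ADF"], 2) == 1.00
        cluster = next(c for c in res.clusters if "NDF" in c)
        assert "ADF" in cluster
        assert "NDF" in res.retained and "ADF" in res.dropped

    def test_energy_pair_grouped_me_retained(self, completed):
        res = screen_collinearity(completed)
        cluster = next(c for c in res.clusters if "ME" in c)
        assert "GE" in cluster
        assert "ME" in res.retained and "GE" in res.dropped

    def test_duplicated_column_groups_with_itself(self, completed):
        df = diets_to_frame(completed)
        df["NDF2"] = df["ndf_pct"]
        res = screen_collinearity(df, variables=["NDF", "NDF2"])
        assert res.correlations.loc["NDF", "NDF2"] == pytest.approx(1.0)
        assert res.clusters == [("NDF", "NDF2")]

    def test_orthogonal_columns_not_grouped(self):
        df = pd.DataFrame({"NDF": [1, -1, 1, -1], "EE": [1, 1, -1, -1]},
                          dtype=float)
        res = screen_collinearity(df, variables=["NDF", "EE"])
        assert res.clusters == []
        assert set(res.retained) == {"NDF", "EE"}

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"NDF": [1.0, 2.0, 3.0], "EE": [4.0, 4.0, 4.0]})
        with pytest.raises(ZeroVarianceError, match="EE"):
            screen_collinearity(df, variables=["NDF", "EE"])


class TestCandidateModels:
    def test_twelve_printed_combinations(self):
        cands = candidate_models()
        assert len(cands) == 12
        assert cands[0].predictors == ("ME", "NDF")
        assert all("NDF" in c.predictors for c in cands)
        # all but the two fibre/fat-protein models carry an energy proxy
        no_energy = [
            c.model_id
            for c in cands
            if "ME" not in c.predictors and "GE" not in c.predictors
        ]
        assert no_energy == [3, 10]


class TestFitMixed:
    def test_ols_equivalence_without_equation_heterogeneity(self, completed):
        sim = simulate_predictions(
            completed, SimulationParams(sigma_equation=0.0, seed=3)
        )
        fit = fit_mixed(sim, ("ME", "NDF"), standardize=False)
        X = sm.add_constant(sim.frame[["me_mj_kg", "ndf_pct"]])
        ols = sm.OLS(sim.frame["ch4_g_per_kg_dm"], X).fit()
        assert np.allclose(fit.params.values, ols.params.values, atol=1e-4)

    def test_parameter_recovery_within_three_se(self, sim_preds):
        eq = fit_mixed(sim_preds, ("ME", "NDF")).to_equation()
        fit = fit_mixed(sim_preds, ("ME", "NDF"))
        truth = sim_preds.true_params
        for name in ("ME", "NDF"):
            se_raw = fit.bse[name] / fit.scaling.sds[name]
            assert abs(eq.coefficients[name] - truth[name]) <= 3 * se_raw

    def test_noise_free_fit_is_exact(self, completed):
        sim = simulate_predictions(
            completed, SimulationParams(sigma_equation=1.5, sigma_resid=0.0, seed=8)
        )
        fit = fit_mixed(sim, ("ME", "NDF"))
        assert fit.r2 == pytest.approx(1.0, abs=1e-8)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)

    def test_rmse_consistent_with_residuals(self, preds):
        fit = fit_mixed(preds, ("ME", "NDF"))
        assert fit.rmse**2 == pytest.approx(
            float(np.mean(fit.resid**2)), rel=1e-6
        )

    def test_metrics_invariant_to_record_order(self, sim_preds):
        from emeq.equations import PredictionSet

        shuffled = PredictionSet(
            sim_preds.frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        a, b = fit_mixed(sim_preds), fit_mixed(shuffled)
        assert a.r2 == pytest.approx(b.r2, rel=1e-9)
        assert a.rmse == pytest.approx(b.rmse, rel=1e-9)

    def test_group_variance_recovery_over_replicates(self, completed):
        # REML sigma^2_equation across seeded replicates centres on the truth
        truth = 1.5**2
        estimates = []
        for seed in range(100):
            sim = simulate_predictions(completed, SimulationParams(seed=seed))
            estimates.append(fit_mixed(sim, ("ME", "NDF")).var_equation)
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - truth) <= 3 * mc_se

    def test_too_few_groups_rejected(self, sim_preds):
        from emeq.equations import PredictionSet

        one_eq = PredictionSet(
            sim_preds.frame[sim_preds.frame["eq_id"] == "sim-001"].reset_index(
                drop=True
            )
        )
        with pytest.raises(ValueError, match="at least 2"):
            CombinedEquationModel(one_eq)


class TestBackTransform:
    def test_identity_scaling_returns_standardized_coefficients(self, sim_preds):
        raw_fit = fit_mixed(sim_preds, ("ME", "NDF"), standardize=False)
        eq = raw_fit.to_equation()
        assert eq.coefficients["ME"] == pytest.approx(raw_fit.params["ME"])
        assert eq.intercept == pytest.approx(raw_fit.params["intercept"])

    def test_hand_arithmetic_single_predictor(self):
        # mean 10, SD 2, slope* 4, intercept* 20 -> raw slope 2, raw intercept 0
        from emeq.combine import CombinedEquation, ScalingParams

        scaling = ScalingParams(means={"NDF": 10.0}, sds={"NDF": 2.0})
        raw_slope = 4.0 / scaling.sds["NDF"]
        raw_int = 20.0 - 4.0 * scaling.means["NDF"] / scaling.sds["NDF"]
        assert raw_slope == 2.0 and raw_int == 0.0
        eq = CombinedEquation(intercept=raw_int, coefficients={"NDF": raw_slope})
        assert eq.predict(NDF=10.0) == pytest.approx(20.0)

    def test_raw_and_standardized_routes_agree(self, preds):
        std_eq = back_transform(fit_mixed(preds, ("ME", "NDF"), standardize=True))
        raw_fit = fit_mixed(preds, ("ME", "NDF"), standardize=False).to_equation()
        assert std_eq.intercept == pytest.approx(raw_fit.intercept, abs=1e-6)
        for name in ("ME", "NDF"):
            assert std_eq.coefficients[name] == pytest.approx(
                raw_fit.coefficients[name], abs=1e-6
            )

    def test_standardized_and_raw_predictions_agree(self, preds):
        fit = fit_mixed(preds, ("ME", "NDF"))
        eq = fit.to_equation()
        Xstd, scaling = standardize(preds, ("ME", "NDF"))
        via_std = (
            fit.params["intercept"]
            + fit.params["ME"] * Xstd["ME"]
            + fit.params["NDF"] * Xstd["NDF"]
        )
        assert np.allclose(eq.predict_frame(preds), via_std, atol=1e-8)

    def test_missing_scaling_rejected(self, sim_preds):
        raw_fit = fit_mixed(sim_preds, ("ME", "NDF"), standardize=False)
        with pytest.raises(ValueError, match="scaling"):
            back_transform(raw_fit)


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        df = pd.DataFrame({"ME": [1, -1, 1, -1], "NDF": [1, 1, -1, -1]}, dtype=float)
        v = vif(df, ["ME", "NDF"])
        assert v["ME"] == pytest.approx(1.0) and v["NDF"] == pytest.approx(1.0)

    def test_two_predictor_closed_form(self):
        # r = 0.682 gives 1/(1 - r^2) = 1.87 (2 dp)
        rng = np.random.default_rng(1)
        r = 0.682
        x = rng.normal(0, 1, 500)
        x = (x - x.mean()) / x.std(ddof=1)
        e = rng.normal(0, 1, 500)
        e = e - e.mean() - x * (e @ x) / (x @ x)  # exactly orthogonal to x
        e /= e.std(ddof=1)
        y = r * x + np.sqrt(1 - r**2) * e  # sample correlation exactly r
        df = pd.DataFrame({"ME": x, "NDF": y})
        got = vif(df, ["ME", "NDF"])["ME"]
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(r, abs=1e-12)
        assert got == pytest.approx(1.0 / (1.0 - r**2), rel=1e-9)
        assert round(got, 2) == 1.87

    def test_exact_collinearity_rejected(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=50), rng.normal(size=50)
        df = pd.DataFrame({"ME": a, "NDF": b, "GE": a + b})
        with pytest.raises(CollinearityError):
            vif(df, ["ME", "NDF", "GE"])


class TestSelectModel:
    def test_parsimony_and_me_priority_pick_model_one_on_packaged_chain(
        self, preds
    ):
        # models 1 (ME+NDF) and 2 (GE+NDF) are numerically equivalent fits
        # (GE is an affine shift of ME), so the energy-proxy preference for
        # ME must break the tie
        fits = fit_all_candidates(preds)
        sel = select_model(fits)
        assert sel.model_id == 1
        assert sel.all_significant
        assert len(sel.table) == 12
        rmse = {f.model_id: f.rmse for f in fits}
        assert rmse[1] == pytest.approx(rmse[2], rel=1e-6)

    def test_single_candidate_selected(self, sim_preds):
        fit = fit_mixed(sim_preds, ("ME", "NDF"), model_id=1)
        sel = select_model([fit])
        assert sel.model_id == 1

    def test_lower_rmse_wins_at_equal_size_and_significance(self, sim_preds):
        good = fit_mixed(sim_preds, ("ME", "NDF"), model_id=1)
        worse = fit_mixed(sim_preds, ("NDF", "FA"), model_id=99)
        if worse.all_slopes_significant:
            sel = select_model([worse, good])
            assert sel.model_id == 1
            assert good.rmse < worse.rmse
        else:
            sel = select_model([worse, good])
            assert sel.model_id == 1
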