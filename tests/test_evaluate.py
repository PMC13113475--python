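import json

import numpy as np
import pytest

from emeq.equations import PredictionSet
from emeq.evaluate import (
    PipelineConfig,
    loo_diet_cv,
    predict_combined,
    reference_extremes,
    run_pipeline,
    sensitivity_loo_equation,
)
from emeq.synth import SimulationParams, simulate_predictions


class TestPredictCombined:
    def test_intercept_at_zero_inputs(self):
        assert predict_combined(0.0, 0.0) == pytest.approx(3.47)

    def test_reference_hand_value(self):
        # 0.33*11.5 + 0.31*32.5 + 3.47
        assert predict_combined(11.5, 32.5) == pytest.approx(17.34, abs=5e-3)

    def test_ndf_marginal_effect(self):
        base = predict_combined(11.5, 32.5)
        assert predict_combined(11.5, 33.5) - base == pytest.approx(0.31)

    @pytest.mark.parametrize("me,ndf", [(-1.0, 30.0), (11.5, np.nan)])
    def test_invalid_inputs_rejected(self, me, ndf):
        with pytest.raises(ValueError):
            predict_combined(me, ndf)


class TestLeaveOneDietOutCV:
    def test_noise_free_predictions_scored_perfectly(self, noise_free_preds):
        report = loo_diet_cv(noise_free_preds)
        assert len(report.per_diet) == 15
        assert np.allclose(report.per_diet["r2"], 1.0, atol=1e-8)
        assert np.allclose(report.per_diet["rmse"], 0.0, atol=1e-8)

    def test_paper_like_variances_give_moderate_skill(self, completed):
        # average held-out skill across seeded replicates at equal
        # between-equation and residual SDs of 1.5 g CH4/kg DM
        means = [
            loo_diet_cv(
                simulate_predictions(completed, SimulationParams(seed=seed))
            ).mean_r2
            for seed in range(10, 20)
        ]
        assert 0.4 <= float(np.mean(means)) <= 0.9

    def test_aggregates_recomputable_from_rows(self, sim_preds):
        report = loo_diet_cv(sim_preds)
        ok = report.per_diet[report.per_diet["converged"]]
        assert report.mean_r2 == pytest.approx(float(ok["r2"].mean()))
        assert report.median_r2 == pytest.approx(float(ok["r2"].median()))
        assert report.min_rmse == pytest.approx(float(ok["rmse"].min()))
        assert report.max_rmse == pytest.approx(float(ok["rmse"].max()))

    def test_two_diets_rejected(self, sim_preds):
        two = PredictionSet(
            sim_preds.frame[
                sim_preds.frame["diet_id"].isin(["1", "2"])
            ].reset_index(drop=True)
        )
        with pytest.raises(ValueError, match="at least 3"):
            loo_diet_cv(two)


class TestSensitivity:
    def test_one_refit_per_removed_equation(self, sim_preds):
        report = sensitivity_loo_equation(sim_preds)
        assert len(report.per_equation) == 32
        assert set(report.per_equation["removed_eq_id"]) == set(sim_preds.eq_ids)

    def test_ranges_bracket_full_data_coefficients(self, sim_preds):
        report = sensitivity_loo_equation(sim_preds)
        for name, (lo, hi) in report.ranges.items():
            assert lo - 1e-12 <= report.full_data[name] <= hi + 1e-12

    def test_no_heterogeneity_no_noise_gives_zero_width(self, completed):
        sim = simulate_predictions(
            completed, SimulationParams(sigma_equation=0.0, sigma_resid=0.0, seed=2)
        )
        report = sensitivity_loo_equation(sim)
        for lo, hi in report.ranges.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-8)

    def test_paper_like_variances_keep_ndf_coefficient_stable(self, sim_preds):
        report = sensitivity_loo_equation(sim_preds)
        truth = sim_preds.true_params["NDF"]
        assert (report.per_equation["NDF"] - truth).abs().max() <= 0.1


class TestPipeline:
    def test_default_run_manifest(self, tmp_path):
        res = run_pipeline(PipelineConfig(), out_dir=tmp_path / "run")
        assert res.manifest["n_prediction_records"] == 480
        assert res.manifest["selected_model"] == res.selection.model_id
        assert (tmp_path / "run" / "manifest.json").exists()
        written = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert written["n_prediction_records"] == 480

    def test_same_seed_runs_are_byte_identical(self, tmp_path):
        for name in ("a", "b"):
            run_pipeline(PipelineConfig(seed=7), out_dir=tmp_path / name)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_forced_model_choice_carried_through(self):
        res = run_pipeline(PipelineConfig(model=3))
        assert res.selection.model_id == 3
        assert "forced" in res.selection.rationale
        assert set(res.equation.coefficients) == {"NDF", "EE"}

    def test_ether_extract_conditionally_irrelevant_on_simulated_truth(
        self, completed
    ):
        # the generative model has no EE effect; conditional on the true
        # predictors its slope should rarely clear the |t| > 2 rule
        # (marginally EE can look significant through its correlation with
        # the energy and fibre content of the diets)
        from emeq.combine import fit_mixed

        non_significant = sum(
            abs(
                fit_mixed(
                    simulate_predictions(completed, SimulationParams(seed=seed)),
                    ("ME", "NDF", "EE"),
                ).tvalues["EE"]
            )
            <= 2.0
            for seed in range(10, 20)
        )
        assert non_significant >= 7

    def test_dry_cow_exclusion_switch(self):
        res = run_pipeline(PipelineConfig(include_dry=False))
        assert res.manifest["n_diets"] == 13
        assert res.manifest["n_prediction_records"] == 32 * 13


class TestReferenceExtremes:
    def test_published_envelope_table(self):
        ref = reference_extremes()
        assert len(ref) == 15
        assert ref["min_g_per_kg_dm"].min() == pytest.approx(12.49)
        assert ref["max_g_per_kg_dm"].max() == pytest.approx(34.27)


class TestPlotting:
    def test_renderers_return_axes(self, sim_preds):
        import matplotlib

        matplotlib.use("Agg")
        from emeq.combine import fit_mixed
        from emeq.plotting import plot_prediction_boxplots, plot_random_effects

        fit = fit_mixed(sim_preds, ("ME", "NDF"))
        ax1 = plot_prediction_boxplots(sim_preds, fit.to_equation())
        ax2 = plot_random_effects(fit)
        assert ax1 is not None and ax2 is not None
        import matplotlib.pyplot as plt

        plt.close("all")
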