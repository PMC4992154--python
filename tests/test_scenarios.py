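"""Threshold choice, counterfactual management scenarios and risk profiles."""

import numpy as np
import pandas as pd
import pytest

from islex.datamodel import INVASIVE_GROUPS
from islex.gee import cloglog, fit_gee, predict_probability
from islex.preprocess import FINAL_MODEL_SPEC, ModelSpec, build_design
from islex.scenarios import (
    apply_scenario,
    choose_threshold,
    odds_ratio,
    predict_extant_summary,
    risk_profile,
    scenario_benefit,
)
from islex.simulate import SimulationParams, simulate_dataset

MANAGED = ("rats", "felids", "pigs", "mustelids_mongooses")


@pytest.fixture(scope="module")
def fit_and_threshold(paper_like_ds, paper_like_design, paper_like_fit):
    choice = choose_threshold(paper_like_fit.fitted, paper_like_design.y, 0.80)
    return paper_like_fit, choice


class TestThreshold:
    def test_four_point_enumeration(self):
        ch = choose_threshold([0.9, 0.8, 0.7, 0.3], [1, 1, 0, 0], 0.8)
        assert ch.threshold == pytest.approx(0.8)
        assert ch.achieved_tpr == 1.0 and ch.achieved_tnr == 1.0

    def test_separated_data_perfect_tnr(self):
        ch = choose_threshold([0.9, 0.85, 0.2, 0.1], [1, 1, 0, 0], 0.8)
        assert ch.achieved_tnr == 1.0

    def test_target_one_threshold_at_min_positive(self):
        fitted = np.array([0.9, 0.6, 0.4, 0.2])
        labels = np.array([1, 1, 0, 0])
        ch = choose_threshold(fitted, labels, 1.0)
        assert ch.threshold <= fitted[labels == 1].min()
        assert ch.achieved_tpr == 1.0

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            choose_threshold([0.5, 0.4], [1, 0], 0.0)
        with pytest.raises(ValueError):
            choose_threshold([0.5, 0.4], [1, 1], 0.8)

    def test_achieves_target_on_study_scale_fit(self, fit_and_threshold):
        _, ch = fit_and_threshold
        assert ch.achieved_tpr >= 0.80
        assert 0 < ch.threshold < 1
        assert len(ch.alternates) == 2


class TestApplyScenario:
    def test_empty_management_is_identity(self, paper_like_ds):
        out = apply_scenario(paper_like_ds, [])
        pd.testing.assert_frame_equal(out.islands, paper_like_ds.islands)

    def test_all_model_groups_zeroed_on_host_islands(self, paper_like_ds):
        out = apply_scenario(paper_like_ds, MANAGED)
        hosts = set(
            paper_like_ds.populations.loc[
                paper_like_ds.populations["extant"] == 1, "island_id"
            ]
        )
        mask = out.islands["island_id"].isin(hosts)
        assert out.islands.loc[mask, list(MANAGED)].to_numpy().sum() == 0
        # input untouched
        assert paper_like_ds.islands[list(MANAGED)].to_numpy().sum() > 0

    def test_island_filter_respected(self, paper_like_ds):
        keep = paper_like_ds.islands["island_id"].iloc[0]
        others = paper_like_ds.islands["island_id"].iloc[1:].tolist()
        out = apply_scenario(paper_like_ds, ["rats"], island_filter=others)
        row_in = out.islands.loc[out.islands["island_id"] == keep]
        row_orig = paper_like_ds.islands.loc[paper_like_ds.islands["island_id"] == keep]
        assert row_in["rats"].to_numpy() == row_orig["rats"].to_numpy()

    def test_unknown_group_rejected(self, paper_like_ds):
        with pytest.raises(ValueError):
            apply_scenario(paper_like_ds, ["weasels"])


class TestExtantPredictions:
    def test_threshold_monotone_classification(self, paper_like_ds, fit_and_threshold):
        fit, ch = fit_and_threshold
        _, _, lo = predict_extant_summary(fit, paper_like_ds, 0.1)
        _, _, mid = predict_extant_summary(fit, paper_like_ds, ch.threshold)
        _, _, hi = predict_extant_summary(fit, paper_like_ds, 0.9)
        assert (
            lo["n_predicted_extirpated"]
            >= mid["n_predicted_extirpated"]
            >= hi["n_predicted_extirpated"]
        )

    def test_threshold_near_one_predicts_none(self, paper_like_ds, fit_and_threshold):
        fit, _ = fit_and_threshold
        _, _, overall = predict_extant_summary(fit, paper_like_ds, 1.0 - 1e-12)
        assert overall["n_predicted_extirpated"] == 0

    def test_aggregates_recount_rows(self, paper_like_ds, fit_and_threshold):
        fit, ch = fit_and_threshold
        table, by_class, overall = predict_extant_summary(fit, paper_like_ds, ch.threshold)
        assert overall["n_extant"] == int((paper_like_ds.populations["extant"] == 1).sum())
        assert overall["n_predicted_extirpated"] == int(table["predicted_extirpated"].sum())
        assert by_class["n_predicted"].sum() == overall["n_predicted_extirpated"]

    def test_empty_extant_set(self, paper_like_ds, fit_and_threshold):
        fit, ch = fit_and_threshold
        from islex.datamodel import Dataset

        pop = paper_like_ds.populations.copy()
        pop = pop[pop["extant"] == 0].reset_index(drop=True)
        ds = Dataset(paper_like_ds.islands, pop)
        _, _, overall = predict_extant_summary(fit, ds, ch.threshold)
        assert overall["n_extant"] == 0


class TestScenarioBenefit:
    def test_identity_scenario_all_zero(self, paper_like_ds, fit_and_threshold):
        fit, ch = fit_and_threshold
        res = scenario_benefit(fit, paper_like_ds, ch.threshold, [])
        assert res.n_preventable == 0
        np.testing.assert_allclose(res.per_population["debt"], 0.0, atol=1e-12)

    def test_preventable_identity_and_debt_sum(self, paper_like_ds, fit_and_threshold):
        fit, ch = fit_and_threshold
        res = scenario_benefit(fit, paper_like_ds, ch.threshold, MANAGED)
        t = res.per_population
        n_both = int(((t["baseline_class"] == 1) & (t["managed_class"] == 1)).sum())
        assert res.n_preventable == res.n_baseline_predicted - n_both
        assert res.total_debt == pytest.approx(
            float((t["baseline_risk"] - t["managed_risk"]).sum()), abs=1e-10
        )

    def test_positive_coefficients_imply_nonincreasing_risk(
        self, paper_like_ds, fit_and_threshold
    ):
        fit, ch = fit_and_threshold
        res = scenario_benefit(fit, paper_like_ds, ch.threshold, ["mustelids_mongooses"])
        assert fit.params["mustelids_mongooses"] > 0
        assert (res.per_population["debt"] >= -1e-12).all()
        assert res.n_preventable >= 0

    def test_rat_only_truth_gives_positive_benefit(self):
        truth = {"intercept": -2.0, "rats": 1.8}
        params = SimulationParams(n_islands=600, seed=80, true_beta=truth)
        ds = simulate_dataset(params)
        spec = ModelSpec(("rats", "ln_area", "human_presence"))
        dm = build_design(ds, spec)
        fit = fit_gee(dm, warn=False)
        ch = choose_threshold(fit.fitted, dm.y, 0.8)
        res = scenario_benefit(fit, ds, ch.threshold, ["rats"])
        assert res.preventable_fraction > 0
        assert (res.per_population["debt"] >= -1e-12).all()

    def test_negative_coefficient_reported_not_clipped(self):
        """A protective invasive effect yields negative debt when removed."""
        truth = {"intercept": -1.0, "lagomorphs": -1.5}
        params = SimulationParams(n_islands=800, seed=81, true_beta=truth)
        ds = simulate_dataset(params)
        spec = ModelSpec(("lagomorphs", "ln_area"))
        dm = build_design(ds, spec)
        fit = fit_gee(dm, warn=False)
        assert fit.params["lagomorphs"] < 0
        ch = choose_threshold(fit.fitted, dm.y, 0.8)
        res = scenario_benefit(fit, ds, ch.threshold, ["lagomorphs"])
        assert (res.per_population["debt"] < 0).any()
        assert res.total_debt < 0


PROFILE = {
    "class_volancy": "volant_bird",
    "ln_area": np.log(134.0),
    "precipitation": 1762.0,
    "human_presence": 1,
    "felids": 0,
    "rats": 0,
    "pigs": 0,
    "mustelids_mongooses": 0,
}


class TestOddsRatioAndProfiles:
    def test_identical_profiles_give_one(self, fit_and_threshold):
        fit, _ = fit_and_threshold
        assert odds_ratio(fit, PROFILE, PROFILE) == pytest.approx(1.0, abs=1e-12)

    def test_odds_arithmetic(self):
        # p_a = 0.5 and p_b = 0.25 -> OR = (1)/(1/3) = 3, independent of model
        assert (0.5 / 0.5) / (0.25 / 0.75) == pytest.approx(3.0)

    def test_matches_hand_computation_through_link(self, fit_and_threshold):
        fit, _ = fit_and_threshold
        prof_rats = dict(PROFILE, rats=1)
        beta = fit.params
        eta0 = (
            beta["intercept"]
            + beta["class_volancy[volant_bird]"]
            + beta["ln_area"] * PROFILE["ln_area"]
            + beta["precipitation"] * PROFILE["precipitation"]
            + beta["human_presence"]
            + beta["class_volancy[volant_bird]:ln_area"] * PROFILE["ln_area"]
            + beta["class_volancy[volant_bird]:precipitation"] * PROFILE["precipitation"]
        )
        eta1 = eta0 + beta["rats"] + beta["rats:ln_area"] * PROFILE["ln_area"]
        p0, p1 = float(cloglog(eta0)), float(cloglog(eta1))
        want = (p1 / (1 - p1)) / (p0 / (1 - p0))
        assert odds_ratio(fit, prof_rats, PROFILE) == pytest.approx(want, rel=1e-10)

    def test_flat_curve_for_zero_coefficient_sweep(self, fit_and_threshold):
        fit, _ = fit_and_threshold
        params = fit.params.copy()
        zeroed = fit
        # sweep a variable after zeroing its coefficients via a modified profile:
        # mean_temperature is not in the model spec, so sweeping it is an error;
        # instead sweep precipitation with all precip coefficients zeroed
        import dataclasses

        params[[c for c in params.index if "precipitation" in c]] = 0.0
        zeroed = dataclasses.replace(fit, params=params)
        curves = risk_profile(
            zeroed, "precipitation", [0.0, 1000.0, 3000.0], PROFILE
        )
        assert curves["risk"].nunique() == 1

    def test_positive_invasive_shifts_curve_up(self, fit_and_threshold):
        fit, _ = fit_and_threshold
        curves = risk_profile(
            fit,
            "ln_area",
            np.linspace(-3, 8, 12),
            PROFILE,
            scenarios={"clean": {}, "mustelids": {"mustelids_mongooses": 1}},
        )
        clean = curves[curves["scenario"] == "clean"]["risk"].to_numpy()
        must = curves[curves["scenario"] == "mustelids"]["risk"].to_numpy()
        assert (must >= clean).all()

    def test_rat_area_interaction_curves_converge(self, fit_and_threshold):
        """Negative rat×area coefficient: rat effect fades on large islands."""
        fit, _ = fit_and_threshold
        assert fit.params["rats:ln_area"] < 0
        sweep = np.linspace(-4, 10, 8)
        curves = risk_profile(
            fit,
            "ln_area",
            sweep,
            dict(PROFILE, human_presence=0),
            scenarios={"norat": {}, "rat": {"rats": 1}},
        )
        norat = curves[curves["scenario"] == "norat"]["risk"].to_numpy()
        rat = curves[curves["scenario"] == "rat"]["risk"].to_numpy()
        gap = np.log(rat / (1 - rat)) - np.log(norat / (1 - norat))
        assert gap[0] > gap[-1]

    def test_categorical_sweep_rejected(self, fit_and_threshold):
        fit, _ = fit_and_threshold
        with pytest.raises(ValueError):
            risk_profile(fit, "class_volancy", [0, 1], PROFILE)
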