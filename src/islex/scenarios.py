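"""Threshold classification, management counterfactuals and risk profiles.

The fitted model yields a continuous extirpation risk per population; a
logistic threshold converts risk into a binary extirpation/persistence call.
Because missing a true extirpation is costlier than a false alarm in a
conservation setting, the default threshold is chosen to achieve a true-
positive rate of 80% on the observed outcomes, maximizing the true-negative
rate subject to that constraint.

Counterfactual scenarios zero out chosen invasive groups on chosen islands
and re-predict.  A predicted extirpation that flips to predicted persistence
under management is *preventable*; the per-population drop in risk is the
extinction debt that management would eliminate.

Odds ratios are computed from predicted probabilities at explicit covariate
profiles (odds(p_a)/odds(p_b)) because under a cloglog link exponentiated
coefficients are not odds ratios.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CLASS_VOLANCY_LEVELS, INVASIVE_GROUPS, Dataset
from .gee import GEEFit, predict_probability
from .preprocess import build_design, encode_profiles

__all__ = [
    "ThresholdChoice",
    "ScenarioResult",
    "choose_threshold",
    "apply_scenario",
    "predict_extant_summary",
    "scenario_benefit",
    "odds_ratio",
    "risk_profile",
]


@dataclasses.dataclass
class ThresholdChoice:
    """A risk threshold with its achieved operating characteristics."""

    threshold: float
    achieved_tpr: float
    achieved_tnr: float
    target_tpr: float
    alternates: list[tuple[float, float, float]]  # (threshold, tpr, tnr)


def _tpr_tnr(fitted: np.ndarray, labels: np.ndarray, t: float) -> tuple[float, float]:
    pred = fitted >= t
    pos = labels == 1
    tpr = float(pred[pos].mean()) if pos.any() else np.nan
    tnr = float((~pred[~pos]).mean()) if (~pos).any() else np.nan
    return tpr, tnr


def choose_threshold(
    fitted,
    labels,
    target_tpr: float = 0.80,
    extra_targets: Sequence[float] = (0.70, 0.90),
) -> ThresholdChoice:
    """Smallest-cost threshold achieving at least the target sensitivity.

    Among candidate thresholds (the observed fitted values) with
    TPR ≥ ``target_tpr`` on the observed outcomes, returns the one with the
    highest TNR, breaking ties towards the larger threshold.  ``extra_targets``
    give alternate operating points for sensitivity analysis.
    """
    if not (0 < target_tpr <= 1):
        raise ValueError("target_tpr must lie in (0, 1]")
    fitted = np.asarray(fitted, float)
    labels = np.asarray(labels, int)
    if labels.min() == labels.max():
        raise ValueError("both outcome classes are required to choose a threshold")

    def _pick(tgt: float) -> tuple[float, float, float]:
        cand = np.unique(fitted)
        best = None
        for t in cand:
            tpr, tnr = _tpr_tnr(fitted, labels, t)
            if tpr >= tgt:
                key = (tnr, t)
                if best is None or key >= best[0]:
                    best = (key, (float(t), tpr, tnr))
        assert best is not None  # t = min(fitted) always gives TPR = 1
        return best[1]

    t, tpr, tnr = _pick(target_tpr)
    alternates = [_pick(a) for a in extra_targets]
    return ThresholdChoice(
        threshold=t,
        achieved_tpr=tpr,
        achieved_tnr=tnr,
        target_tpr=target_tpr,
        alternates=alternates,
    )


def apply_scenario(
    ds: Dataset,
    managed_groups: Sequence[str],
    island_filter: Sequence | None = None,
) -> Dataset:
    """Dataset with the managed invasive groups eradicated on selected islands.

    Pure transformation: presence (and any eradication flag) of each managed
    group is set to 0 on the filtered islands — by default every island that
    hosts at least one extant threatened population.  The input dataset is
    untouched.
    """
    unknown = set(managed_groups) - set(INVASIVE_GROUPS)
    if unknown:
        raise ValueError(f"unknown invasive groups: {sorted(unknown)}")
    out = ds.copy()
    if island_filter is None:
        hosts = set(ds.populations.loc[ds.populations["extant"] == 1, "island_id"])
    else:
        hosts = set(island_filter)
    mask = out.islands["island_id"].isin(hosts)
    for g in managed_groups:
        out.islands.loc[mask, g] = 0
        ecol = f"eradicated_{g}"
        if ecol in out.islands.columns:
            out.islands.loc[mask, ecol] = 0
    return out


def _extant_design(fit: GEEFit, ds: Dataset):
    """Design rows for extant populations under current invasive presence."""
    extant = Dataset(
        ds.islands,
        ds.populations.loc[ds.populations["extant"] == 1].reset_index(drop=True),
        ds.provenance,
    )
    dm = build_design(extant, fit.spec, use_historical_presence=False)
    return extant, dm


def predict_extant_summary(fit: GEEFit, ds: Dataset, threshold: float):
    """Classify every extant population at the threshold; aggregate by group.

    Returns ``(table, by_class, overall)``: the per-population risk table,
    per-class/volancy counts and fractions predicted extirpated, and overall
    counts including single-island endemics.
    """
    if not len(ds.populations) or not (ds.populations["extant"] == 1).any():
        return (
            pd.DataFrame(
                columns=["species_id", "island_id", "class_volancy", "risk", "predicted_extirpated"]
            ),
            pd.DataFrame(columns=["class_volancy", "n", "n_predicted", "frac_predicted"]),
            {"n_extant": 0, "n_predicted_extirpated": 0, "frac_predicted_extirpated": float("nan")},
        )
    extant, dm = _extant_design(fit, ds)
    risk = predict_probability(fit, dm)
    table = dm.row_index.copy()
    meta = extant.populations.set_index(["species_id", "island_id"])
    table["class_volancy"] = meta.loc[
        pd.MultiIndex.from_frame(table), "class_volancy"
    ].to_numpy()
    table["single_island_endemic"] = meta.loc[
        pd.MultiIndex.from_frame(table[["species_id", "island_id"]]), "single_island_endemic"
    ].to_numpy()
    table["risk"] = risk
    table["predicted_extirpated"] = (risk >= threshold).astype(int)

    by_class = (
        table.groupby("class_volancy", observed=True)
        .agg(n=("risk", "size"), n_predicted=("predicted_extirpated", "sum"))
        .reindex([c for c in CLASS_VOLANCY_LEVELS])
        .dropna()
        .reset_index()
    )
    by_class["frac_predicted"] = by_class["n_predicted"] / by_class["n"]
    sie = table[table["single_island_endemic"] == 1]
    overall = {
        "n_extant": int(len(table)),
        "n_predicted_extirpated": int(table["predicted_extirpated"].sum()),
        "frac_predicted_extirpated": float(table["predicted_extirpated"].mean()),
        "n_predicted_single_island_endemic": int(sie["predicted_extirpated"].sum()),
    }
    return table, by_class, overall


@dataclasses.dataclass
class ScenarioResult:
    """Baseline vs managed predictions for extant populations."""

    per_population: pd.DataFrame
    managed_groups: tuple[str, ...]
    threshold: float
    n_baseline_predicted: int
    n_preventable: int
    preventable_fraction: float
    total_debt: float
    by_class: pd.DataFrame


def scenario_benefit(
    fit: GEEFit,
    ds: Dataset,
    threshold: float,
    managed_groups: Sequence[str],
    island_filter: Sequence | None = None,
) -> ScenarioResult:
    """Predicted benefit of eradicating the managed groups.

    Per extant population: baseline vs managed risk and classification, the
    preventable flag (predicted extirpated at baseline, predicted persisting
    under management) and the extinction debt (risk reduction).  Negative
    debt (a group whose estimated effect is protective) is reported, not
    clipped.
    """
    base_table, _, _ = predict_extant_summary(fit, ds, threshold)
    managed_ds = apply_scenario(ds, managed_groups, island_filter)
    managed_table, _, _ = predict_extant_summary(fit, managed_ds, threshold)
    t = base_table.rename(columns={"risk": "baseline_risk", "predicted_extirpated": "baseline_class"})
    t["managed_risk"] = managed_table["risk"].to_numpy()
    t["managed_class"] = managed_table["predicted_extirpated"].to_numpy()
    t["preventable"] = ((t["baseline_class"] == 1) & (t["managed_class"] == 0)).astype(int)
    t["debt"] = t["baseline_risk"] - t["managed_risk"]
    t = t.sort_values("debt", ascending=False).reset_index(drop=True)

    by_class = (
        t.groupby("class_volancy", observed=True)
        .agg(
            n=("debt", "size"),
            n_baseline=("baseline_class", "sum"),
            n_preventable=("preventable", "sum"),
            total_debt=("debt", "sum"),
        )
        .reset_index()
    )
    n_base = int(t["baseline_class"].sum())
    n_prev = int(t["preventable"].sum())
    return ScenarioResult(
        per_population=t,
        managed_groups=tuple(managed_groups),
        threshold=float(threshold),
        n_baseline_predicted=n_base,
        n_preventable=n_prev,
        preventable_fraction=n_prev / n_base if n_base else float("nan"),
        total_debt=float(t["debt"].sum()),
        by_class=by_class,
    )


def _profile_frame(profile: Mapping, spec) -> pd.DataFrame:
    row = dict(profile)
    if "class_volancy" not in row:
        raise ValueError("profile must include class_volancy")
    return pd.DataFrame([row])


def odds_ratio(fit: GEEFit, profile_a: Mapping, profile_b: Mapping) -> float:
    """Odds ratio of predicted extirpation between two covariate profiles.

    Each profile maps every main-effect term of the fitted model (including
    ``class_volancy``) to a value; risks come from the fitted model through
    the link, and the ratio is odds(p_a)/odds(p_b).
    """
    pa = float(
        predict_probability(fit, encode_profiles(_profile_frame(profile_a, fit.spec), fit.spec, fit.columns))[0]
    )
    pb = float(
        predict_probability(fit, encode_profiles(_profile_frame(profile_b, fit.spec), fit.spec, fit.columns))[0]
    )
    for p in (pa, pb):
        if p <= 0.0 or p >= 1.0:
            raise ValueError("profile risk at 0 or 1; odds undefined")
    return (pa / (1 - pa)) / (pb / (1 - pb))


def risk_profile(
    fit: GEEFit,
    sweep_variable: str,
    sweep_values: Sequence[float],
    fixed_profile: Mapping,
    scenarios: Mapping[str, Mapping] | None = None,
) -> pd.DataFrame:
    """Predicted risk along one covariate sweep, per invasive scenario.

    ``fixed_profile`` holds the non-swept covariates (e.g. median
    precipitation, a class/volancy level); each scenario is a set of
    overrides (typically invasive presence flags).  Returns a long table
    (scenario, sweep value, risk) ready for plotting.
    """
    if sweep_variable == "class_volancy":
        raise ValueError("cannot sweep a categorical variable")
    scenarios = scenarios or {"baseline": {}}
    out = []
    for name, overrides in scenarios.items():
        prof = dict(fixed_profile)
        prof.update(overrides)
        rows = pd.DataFrame([prof] * len(sweep_values))
        rows[sweep_variable] = np.asarray(sweep_values, float)
        X = encode_profiles(rows, fit.spec, fit.columns)
        risk = predict_probability(fit, X)
        out.append(
            pd.DataFrame(
                {"scenario": name, sweep_variable: sweep_values, "risk": risk}
            )
        )
    return pd.concat(out, ignore_index=True)
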