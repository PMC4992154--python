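"""QICu-based all-subsets model selection with forced-term screening.

The selection protocol, applied to main effects first and interactions
second:

1. screen covariates (correlation, rarity, missingness);
2. for each model order k, fit *every* k-subset of the candidate main
   effects and rank by QICu; models within ΔQICu < 2 of the best form the
   top set;
3. compute the in-sample MSE of the (QICu-weight-averaged) top model per
   order and choose the smallest order beyond which the relative MSE
   improvement falls under a tolerance;
4. starting from the best model of the chosen order, test each a-priori
   candidate interaction sequentially, retaining it only if it lowers QICu
   by more than a conservative margin (default 10);
5. finally, test forced term bundles (rats and rat×area, added for their
   management relevance even if unselected) with a stricter margin
   (default 20).

Model averaging uses Akaike-type weights w ∝ exp(−ΔQICu/2) with zero-filled
(full) averaging: a coefficient absent from a model contributes zero.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import Dataset
from .gee import GEEFit, cloglog, fit_gee, fit_mse
from .preprocess import DesignMatrix, ModelSpec, SpecificationError, build_design

__all__ = [
    "RankedModel",
    "SelectionConfig",
    "SelectionResult",
    "TermPool",
    "all_subsets_rank",
    "average_top_models",
    "order_curve_and_choice",
    "screen_and_force",
    "run_selection",
    "final_model_from_audit",
]


@dataclasses.dataclass
class RankedModel:
    """One candidate model in an all-subsets ranking."""

    terms: tuple[str, ...]
    qicu: float
    delta: float  # ΔQICu to the best converged model of the same order
    converged: bool
    params: pd.Series
    mse: float

    @property
    def in_top(self) -> bool:
        return self.converged and self.delta < 2.0


class TermPool:
    """Pre-encoded design over all candidate main effects.

    Fitting a subset of candidates then reduces to selecting columns of one
    design matrix, which makes exhaustive enumeration of thousands of
    candidate models tractable.
    """

    def __init__(
        self,
        ds: Dataset,
        candidates: Sequence[str],
        reference_level: str = "amphibian",
        use_historical_presence: bool = True,
    ):
        self.candidates = tuple(candidates)
        self.reference_level = reference_level
        spec = ModelSpec(self.candidates, (), reference_level)
        self.dm = build_design(ds, spec, use_historical_presence)
        self.term_cols = {
            t: [c for c, tt in self.dm.term_map.items() if tt == t]
            for t in self.candidates
        }
        # warm start for subset fits: the all-candidates fit, restricted to the
        # subset's columns (absent columns start at 0)
        self._full_fit = fit_gee(self.dm, warn=False)

    def design_for(self, mains: Sequence[str]) -> DesignMatrix:
        cols = ["intercept"]
        for t in mains:
            if t not in self.term_cols:
                raise SpecificationError(f"term {t!r} is not a pool candidate")
            cols.extend(self.term_cols[t])
        spec = ModelSpec(tuple(mains), (), self.reference_level)
        return DesignMatrix(
            y=self.dm.y,
            X=self.dm.X[cols],
            cluster_index=self.dm.cluster_index,
            term_map={c: self.dm.term_map[c] for c in cols},
            spec=spec,
            n_dropped=self.dm.n_dropped,
        )

    def fit(self, mains: Sequence[str], tol: float = 1e-6) -> GEEFit:
        dm = self.design_for(mains)
        start = self._full_fit.params.reindex(dm.columns, fill_value=0.0).to_numpy()
        return fit_gee(dm, tol=tol, start_params=start, warn=False, polish=False)


def all_subsets_rank(
    pool: TermPool, order: int, candidates: Sequence[str] | None = None
) -> list[RankedModel]:
    """Fit every ``order``-subset of the candidates and rank by QICu.

    Ties are broken lexicographically by term names.  Non-convergent fits are
    kept in the list, flagged, and excluded from the Δ reference and the top
    set.
    """
    cands = tuple(candidates) if candidates is not None else pool.candidates
    if order > len(cands):
        raise ValueError(f"order {order} exceeds number of candidates {len(cands)}")
    records = []
    for subset in itertools.combinations(cands, order):
        try:
            f = pool.fit(subset)
            rec = RankedModel(
                terms=subset,
                qicu=f.qicu,
                delta=np.nan,
                converged=f.converged,
                params=f.params,
                mse=f.mse,
            )
        except np.linalg.LinAlgError:  # rank-deficient subset: flag, keep listed
            rec = RankedModel(subset, np.nan, np.nan, False, pd.Series(dtype=float), np.nan)
        records.append(rec)
    conv = [r for r in records if r.converged]
    best = min(r.qicu for r in conv) if conv else np.nan
    for r in records:
        r.delta = r.qicu - best if r.converged else np.nan
    records.sort(key=lambda r: (not r.converged, r.qicu if r.converged else np.inf, r.terms))
    return records


def average_top_models(top: Sequence[RankedModel]) -> pd.Series:
    """QICu-weight averaged coefficients over the top model set.

    Weights w_m ∝ exp(−Δ_m/2) sum to one; averaging is zero-filled over the
    union of design columns (a term absent from a model contributes 0).
    """
    if not top:
        raise ValueError("top model set is empty")
    deltas = np.array([m.delta for m in top], float)
    w = np.exp(-deltas / 2)
    w /= w.sum()
    cols: list[str] = []
    for m in top:
        for c in m.params.index:
            if c not in cols:
                cols.append(c)
    avg = pd.Series(0.0, index=cols)
    for wi, m in zip(w, top):
        avg[m.params.index] += wi * m.params
    return avg


@dataclasses.dataclass
class OrderCurve:
    per_order: pd.DataFrame  # order, best terms, n_top, qicu_best, mse
    chosen_order: int
    top_by_order: dict[int, list[RankedModel]]


def order_curve_and_choice(
    pool: TermPool,
    max_order: int | None = None,
    rel_tol: float = 0.005,
    candidates: Sequence[str] | None = None,
) -> OrderCurve:
    """MSE of the averaged top model per order, and the diminishing-returns choice.

    Chooses the smallest order k whose relative MSE improvement to order k+1
    is below ``rel_tol`` (default 0.5%); if the improvement never stalls the
    maximum order is chosen.  A non-monotone curve is handled by the same
    rule (improvements can be negative, which trivially stalls).
    """
    cands = tuple(candidates) if candidates is not None else pool.candidates
    max_order = len(cands) if max_order is None else min(max_order, len(cands))
    rows = []
    top_by_order: dict[int, list[RankedModel]] = {}
    mses = []
    for order in range(1, max_order + 1):
        ranked = all_subsets_rank(pool, order, cands)
        top = [r for r in ranked if r.in_top]
        top_by_order[order] = top
        avg = average_top_models(top)
        union_mains = sorted({t for m in top for t in m.terms})
        dm_u = pool.design_for(union_mains)
        beta = avg.reindex(dm_u.columns, fill_value=0.0)
        fitted = cloglog(dm_u.X.to_numpy(float) @ beta.to_numpy())
        mse = fit_mse(dm_u.y, fitted)
        mses.append(mse)
        rows.append(
            {
                "order": order,
                "n_models": int(math.comb(len(cands), order)),
                "n_top": len(top),
                "best_terms": "+".join(ranked[0].terms),
                "qicu_best": ranked[0].qicu,
                "mse": mse,
            }
        )
    chosen = max_order
    for i in range(len(mses) - 1):
        improvement = (mses[i] - mses[i + 1]) / mses[i] if mses[i] > 0 else 0.0
        if improvement < rel_tol:
            chosen = i + 1
            break
    return OrderCurve(pd.DataFrame(rows), chosen, top_by_order)


def _fit_spec(ds: Dataset, spec: ModelSpec, use_historical_presence: bool = True) -> GEEFit:
    return fit_gee(build_design(ds, spec, use_historical_presence), warn=False)


def screen_and_force(
    base: ModelSpec,
    candidate_interactions: Sequence[tuple[str, str]],
    forced: Sequence[dict],
    ds: Dataset,
    interaction_threshold: float = 10.0,
    forced_threshold: float = 20.0,
    sequential: bool = True,
    audit: list[str] | None = None,
) -> ModelSpec:
    """Interaction screening and forced-term addition by QICu decrease.

    Each candidate interaction is added (with any missing mains) to the
    current model and retained iff QICu falls by more than
    ``interaction_threshold``.  With ``sequential`` (default) retained terms
    stay in the model for subsequent tests; otherwise every candidate is
    tested against the base model and retained ones are added jointly.
    Forced bundles (e.g. rats + rat×area) are added iff their joint addition
    beats ``forced_threshold``.
    """
    audit = audit if audit is not None else []
    current = base
    current_fit = _fit_spec(ds, current)
    audit.append(f"BASE mains={'+'.join(base.main_effects)} QICu={current_fit.qicu:.3f}")

    retained: list[tuple[str, str]] = []
    reference = current_fit
    for pair in candidate_interactions:
        trial_spec = (current if sequential else base).with_terms(interactions=[pair])
        trial = _fit_spec(ds, trial_spec)
        d = (reference if sequential else current_fit).qicu - trial.qicu
        tag = f"interaction {pair[0]}:{pair[1]} dQICu={d:.3f}"
        if trial.converged and d > interaction_threshold:
            retained.append(pair)
            audit.append(f"RETAIN {tag}")
            if sequential:
                current = trial_spec
                reference = trial
        else:
            audit.append(f"REJECT {tag}")
    if not sequential and retained:
        current = base.with_terms(interactions=retained)
        reference = _fit_spec(ds, current)

    for bundle in forced:
        mains = tuple(bundle.get("mains", ()))
        inters = tuple(tuple(p) for p in bundle.get("interactions", ()))
        trial_spec = current.with_terms(mains=mains, interactions=inters)
        if trial_spec == current:
            audit.append(f"FORCED-SKIP {bundle} (already in model)")
            continue
        trial = _fit_spec(ds, trial_spec)
        d = reference.qicu - trial.qicu
        label = "+".join(mains) + "".join(f"+{a}:{b}" for a, b in inters)
        if trial.converged and d > forced_threshold:
            current = trial_spec
            reference = trial
            audit.append(f"FORCE-ADD {label} dQICu={d:.3f}")
        else:
            audit.append(f"FORCE-REJECT {label} dQICu={d:.3f}")
    audit.append(
        "FINAL mains=" + "+".join(current.main_effects)
        + " interactions=" + ",".join(f"{a}:{b}" for a, b in current.interactions)
    )
    return current


@dataclasses.dataclass
class SelectionConfig:
    max_order: int | None = None
    rel_tol: float = 0.005
    interaction_threshold: float = 10.0
    forced_threshold: float = 20.0
    sequential: bool = True
    candidate_interactions: tuple[tuple[str, str], ...] | None = None
    forced: tuple[dict, ...] = (
        {"mains": ("rats",), "interactions": (("rats", "ln_area"),)},
    )


@dataclasses.dataclass
class SelectionResult:
    per_order: pd.DataFrame
    chosen_order: int
    base_model: ModelSpec
    retained_interactions: list[tuple[str, str]]
    final_model: ModelSpec
    final_fit: GEEFit
    audit_log: list[str]
    screening: object  # ScreeningReport


def default_candidate_interactions(base: ModelSpec) -> tuple[tuple[str, str], ...]:
    """A-priori interaction hypotheses restricted to the base-model terms.

    Families, in testing order: invasive×area, invasive×precipitation,
    class×area, class×precipitation, class×invasive.
    """
    from .datamodel import INVASIVE_GROUPS

    mains = base.main_effects
    invasives = [g for g in INVASIVE_GROUPS if g in mains]
    out: list[tuple[str, str]] = []
    if "ln_area" in mains:
        out += [(g, "ln_area") for g in invasives]
    if "precipitation" in mains:
        out += [(g, "precipitation") for g in invasives]
    if "class_volancy" in mains and "ln_area" in mains:
        out.append(("class_volancy", "ln_area"))
    if "class_volancy" in mains and "precipitation" in mains:
        out.append(("class_volancy", "precipitation"))
    if "class_volancy" in mains:
        out += [("class_volancy", g) for g in invasives]
    return tuple(out)


def run_selection(
    ds: Dataset,
    candidates: Sequence[str] | None = None,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """The full selection protocol: screen → all-subsets per order →
    diminishing-returns order choice → interaction screening → forced terms.

    Deterministic given the dataset and configuration.
    """
    from .preprocess import covariate_screen

    config = config or SelectionConfig()
    audit: list[str] = []
    screening = covariate_screen(ds)
    if candidates is None:
        candidates = screening.candidate_terms
    audit.append(
        "SCREEN candidates=" + "+".join(candidates)
        + " excluded_rare=" + ",".join(screening.excluded_rare_groups)
        + " excluded_missing=" + ",".join(screening.excluded_missing)
    )
    pool = TermPool(ds, candidates)
    curve = order_curve_and_choice(pool, config.max_order, config.rel_tol)
    audit.append(f"ORDER chosen={curve.chosen_order} (rel_tol={config.rel_tol})")
    best = curve.top_by_order[curve.chosen_order][0]
    base = ModelSpec(tuple(best.terms), (), pool.reference_level)
    cand_inter = (
        config.candidate_interactions
        if config.candidate_interactions is not None
        else default_candidate_interactions(base)
    )
    final = screen_and_force(
        base,
        cand_inter,
        config.forced,
        ds,
        interaction_threshold=config.interaction_threshold,
        forced_threshold=config.forced_threshold,
        sequential=config.sequential,
        audit=audit,
    )
    final_fit = _fit_spec(ds, final)
    return SelectionResult(
        per_order=curve.per_order,
        chosen_order=curve.chosen_order,
        base_model=base,
        retained_interactions=[p for p in final.interactions],
        final_model=final,
        final_fit=final_fit,
        audit_log=audit,
        screening=screening,
    )


def final_model_from_audit(audit_log: Iterable[str], reference_level: str = "amphibian") -> ModelSpec:
    """Reconstruct the final ModelSpec from an audit log (replay check)."""
    final_line = None
    for line in audit_log:
        if line.startswith("FINAL "):
            final_line = line
    if final_line is None:
        raise ValueError("audit log has no FINAL line")
    parts = dict(
        kv.split("=", 1) for kv in final_line[len("FINAL "):].split(" ") if "=" in kv
    )
    mains = tuple(t for t in parts["mains"].split("+") if t)
    inters = tuple(
        tuple(p.split(":")) for p in parts.get("interactions", "").split(",") if p
    )
    return ModelSpec(mains, inters, reference_level)  # type: ignore[arg-type]
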