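# islex

Clustered extirpation-risk modelling for island vertebrate populations.

Invasive mammals are the leading driver of extinctions on islands.  Given a
global table of islands (size, climate, human presence, which of 12
invasive-mammal groups occur there) and a table of threatened-vertebrate
populations on those islands (taxonomic class/volancy, extirpated after
AD 1500 or persisting), `islex` answers three questions conservation
planners ask:

1. **What drives extirpation?** A marginal binomial regression with a
   complementary log-log link, fitted by generalized estimating equations
   (GEE) with an exchangeable working correlation by island — populations on
   one island are not independent — and cluster-robust (sandwich) standard
   errors:

       g(p_ij) = ln(−ln(1 − p_ij)) = x_ijᵀ β,   Corr(y_ij, y_ik) = α

   Model structure is chosen by all-subsets QICu ranking per model order
   (QICu = −2·QL + 2p), an MSE-by-order diminishing-returns rule, and
   conservative ΔQICu screening of a-priori interactions.
2. **How well does it predict?** Repeated island-level 10-fold
   cross-validation with ROC/AUC and four prediction-error statistics,
   plus leave-one-island-out influence diagnostics.
3. **What would management buy?** A risk threshold at 80% sensitivity
   classifies extant populations; counterfactual eradication scenarios
   (e.g. remove rats, cats, pigs, mustelids/mongooses) recompute risk and
   count *preventable* predicted extirpations and the per-population
   extinction debt (baseline risk − managed risk).

A calibrated synthetic-data generator (`islex.simulate`) reproduces the
study conditions — ~1,000 islands, ~2,600 populations, 25% extirpation
prevalence, island-level outcome correlation via a Gaussian copula — with a
known ground-truth model, so the entire pipeline is testable without any
external database.  See `docs/methods.md` for the statistical details.

The intended users are quantitative conservation scientists; everything is
a plain function over pandas DataFrames, with a thin `islex` CLI on top.

## Worked example

```python
import numpy as np
from islex import (FINAL_MODEL_SPEC, build_design, choose_threshold,
                   cross_validate, fit_gee, make_fixture, roc_auc,
                   scenario_benefit)

ds = make_fixture("paper_like")          # synthetic study, known ground truth
dm = build_design(ds, FINAL_MODEL_SPEC)  # 34 columns, clustered by island
fit = fit_gee(dm)
print(f"alpha={fit.alpha:.3f}  QICu={fit.qicu:.1f}  "
      f"rats: {fit.params['rats']:+.2f} (SE {fit.robust_se()['rats']:.2f})")

auc, _ = roc_auc(fit.fitted, dm.y)
_, cv = cross_validate(ds, FINAL_MODEL_SPEC, k=10, repeats=10, seed=11)
print(f"full-data AUC={auc:.3f}  CV AUC={cv['mean_auc']:.3f} (sd {cv['sd_auc']:.3f})")

ch = choose_threshold(fit.fitted, dm.y, target_tpr=0.80)
res = scenario_benefit(fit, ds, ch.threshold,
                       ["rats", "felids", "pigs", "mustelids_mongooses"])
print(f"TNR at 80% TPR: {ch.achieved_tnr:.2f}  "
      f"preventable: {res.n_preventable}/{res.n_baseline_predicted} "
      f"({100*res.preventable_fraction:.0f}%)  debt={res.total_debt:.0f}")
```

Output:

```
alpha=0.180  QICu=2448.0  rats: +0.96 (SE 0.13)
full-data AUC=0.765  CV AUC=0.746 (sd 0.033)
TNR at 80% TPR: 0.59  preventable: 508/826 (62%)  debt=174
```

Read: within-island correlation is modest (α ≈ 0.18); rats roughly double
the log-hazard of extirpation on a median island; the model separates
extirpated from persisting populations well out of sample (AUC ≈ 0.75); and
eradicating the four modelled invasive groups would flip about 6 in 10 of
the predicted future extirpations to predicted persistence, eliminating an
expected ~174 extirpations' worth of summed risk.

The same analysis from the shell:

```sh
islex simulate --preset paper_like --seed 42 --out-islands isl.csv --out-populations pop.csv
islex summarize --islands isl.csv --populations pop.csv
islex fit       --islands isl.csv --populations pop.csv --out fit.json
islex validate  --islands isl.csv --populations pop.csv --k 10 --repeats 10 --seed 1 --out cv/
islex predict   --fit fit.json --islands isl.csv --populations pop.csv --out pred/
islex scenario  --fit fit.json --islands isl.csv --populations pop.csv \
                --manage rats,felids,pigs,mustelids_mongooses --out scen/
islex select    --islands isl.csv --populations pop.csv --max-order 8 --out sel/
```

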