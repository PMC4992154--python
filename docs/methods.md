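# Methods

## The model

The unit of analysis is one breeding population: a native threatened
vertebrate species on one island. Its outcome is binary — extirpated after
AD 1500 (y = 1) or persisting (y = 0). Populations sharing an island are not
independent (storms, disease outbreaks, unmeasured island history), so the
marginal regression is estimated with generalized estimating equations
(GEE), clustered by island, with an exchangeable working correlation: every
pair of populations on the same island shares one correlation parameter α.

Because roughly three quarters of outcomes are zeros, the link is the
asymmetric complementary log-log,

    g(p) = ln(−ln(1 − p)),     p = 1 − exp(−exp(xᵀβ)),

rather than the symmetric logit. Coefficients β live on the cloglog scale;
effects on the odds scale are therefore always computed by pushing two
covariate profiles through the link and taking the ratio of odds of the two
predicted risks — exponentiated coefficients are *not* odds ratios under
this link.

Estimation solves Σᵢ Dᵢᵀ Vᵢ⁻¹ (yᵢ − μᵢ) = 0 by Fisher scoring, with moment
updates of the scale φ = Σe²/(n−p) and of α from the cross-products of
Pearson residuals (Liang–Zeger convention: the denominator subtracts p).
The exchangeable structure admits the rank-one closed-form inverse
R⁻¹ = (1−α)⁻¹[I − α/(1+(nᵢ−1)α) J], so a fit touches only per-cluster sums
and runs in O(np) per iteration; a dense-inversion cross-check is part of
the test suite. Convergence requires max|Δβ| < 1e−8 (configurable) together
with a stable α, followed by Newton polishing at frozen (α, φ) that drives
the estimating-equation residual to ~1e−10. Inference uses the cluster-robust
sandwich covariance B⁻¹MB⁻¹, which is consistent even if the exchangeable
working correlation is wrong; the model-based covariance is also reported.

Degenerate inputs: rank-deficient designs raise an error naming the
collinear columns (via pivoted QR); non-convergence is flagged on the result
rather than raised; fitted risks pinned at the 0/1 boundary trigger a
quasi-separation warning; fitted values are clamped to [1e−12, 1−1e−12]
inside the quasi-likelihood.

## Model selection

Model comparison uses QICu = −2·QL + 2p, where QL is the independence
binomial quasi-likelihood at the fitted values and p counts design columns.
The protocol:

1. **Screen.** Pairwise Pearson correlations among continuous covariates
   (|r| > 0.7 flagged; raw elevation is replaced by the residual of
   ln(elevation+1) on ln(area), which carries the part of topography not
   explained by size); invasive groups on fewer than 10% of islands
   excluded; covariates above a missingness ceiling (body mass) excluded.
   A non-metric-style MDS ordination of invasive groups (classical MDS
   start, SMACOF majorization, Kruskal stress-1 reported) is available as a
   diagnostic for groups that co-occur so tightly they should be merged.
2. **All-subsets per order.** For each order k, every k-subset of the
   (15) candidate main effects is fitted and ranked by QICu; models within
   ΔQICu < 2 of the best form the top set. Ties break lexicographically by
   term name. Non-convergent candidates stay listed but flagged and are
   excluded from the ranking reference — a criterion computed from an
   unconverged fit is meaningless.
3. **Order choice.** The in-sample MSE (Brier score) of the weight-averaged
   top model is computed per order; the chosen order is the smallest k whose
   relative MSE improvement to k+1 falls below 0.5% (configurable). Model
   averaging uses Akaike-type weights w ∝ exp(−ΔQICu/2) with zero-filled
   averaging over the union of columns; conditional averaging is an option.
4. **Interactions.** A-priori candidate interactions are tested
   sequentially and cumulatively (each retained term stays in the model for
   later tests); a term is retained only if it lowers QICu by more than 10,
   a deliberately conservative margin.
5. **Forced terms.** Rats (and rat×area) are tested as a forced bundle with
   a stricter margin (ΔQICu > 20) because of their management relevance; if
   the bundle fails the margin it is rejected and the decision logged.

Every decision is appended to an audit log from which the final model can be
reconstructed (a replay test enforces this).

Subset fits are warm-started from the all-candidates fit restricted to the
subset's columns and skip the final polish, which makes exhaustive
enumeration (2¹⁵ ≈ 33k fits at n ≈ 2.6k) a matter of minutes on one core.

## Validation

Cross-validation is at the island level: whole islands are partitioned into
K = 10 folds (sizes differing by at most one), each fold held out once
against a model refitted on the rest, and the process repeated with fresh
partitions. Each repeat×fold is one validation run reporting mean error,
mean absolute error, SD of error, MSE, and the AUC of held-out rows. AUC is
the Mann–Whitney rank statistic with ties counted ½ — exactly the
concordance probability — cross-checked against an O(n²) brute force in the
tests. Folds whose test rows contain a single outcome class are recorded
and excluded from AUC aggregates, never resampled, so the partition law is
untouched. Influence diagnostics refit the model exactly with each island
deleted (warm-started) and rank islands by the Cook-type form
Δβᵀ Σ_robust⁻¹ Δβ; observation-level refits are run inside the most
influential islands.

## Thresholding and counterfactuals

A risk threshold converts predictions to binary calls. Missing a true
extirpation is treated as costlier than a false alarm, so the default
threshold is the one achieving ≥80% sensitivity on observed outcomes while
maximizing specificity (ties resolved to the larger threshold); alternate
sensitivity targets (70%, 90%) are reported for sensitivity analysis. The
"worst-case" bound is taken at the most conservative (highest-specificity)
configured alternate.

Fitting uses *historical* invasive presence — eradicated groups count as
present, since they shaped the observed extirpations — while prediction for
extant populations uses *current* presence (eradications applied).
Management counterfactuals set chosen groups to absent on islands hosting
extant threatened populations and re-predict: a population predicted
extirpated at baseline but persisting under management is *preventable*, and
its risk reduction is the extinction debt that management would erase.
Negative debt (an estimated protective effect) is reported, not clipped.

## The synthetic-data generator

The generator produces a full study with known ground truth so every stage
is testable offline. It emulates, with defaults calibrated once against the
global study's descriptive aggregates:

| feature | default / target |
|---|---|
| islands | 1,024; areas log-normal, ln-median 2.27 (≈9.7 km²), ln-SD 3.5 |
| human presence | logistic in ln area; ≈54% uninhabited; inhabited islands larger (median ≈10² km²) and wetter |
| precipitation | normal around 1,326 mm + 165·(ln area − mean), truncated at 0 |
| elevation | noisy power law in area (induces the r > 0.7 collinearity handled by the residual transform) |
| invasive occupancy | per-group logistic in (human presence, ln area); ≈73% of islands invaded; uninhabited islands mostly invasive-free or rat/cat-only; mustelids ≈11%; four groups kept under the 10% screening line |
| populations | zero-truncated geometric counts per island (mean 2.6); six-class mix dominated by volant birds and reptiles; species span a geometric number of islands (mean ≈2.1) |
| outcomes | cloglog model with effects signed per the fitted global model (rats/cats/pigs/mustelids/humans harmful; rat effect fading with area; class-specific area and precipitation slopes); ≈25% extirpated |
| dependence | Gaussian copula: shared island factor with latent correlation root-found so the average within-island *outcome* correlation over real marginal pairs matches the requested ρ (default 0.2) |

The copula gives exact marginal risks with tunable dependence — a
generative counterpart to the working-correlation assumption, which itself
specifies no mechanism. Calibrating the latent correlation against sampled
within-island marginal pairs (rather than one average marginal) removes the
bias that heterogeneous risks otherwise induce. RNG consumption is ordered
island-by-island so enlarging one island leaves other islands' draws alone.

What the generator does **not** emulate: spatial or phylogenetic structure,
archipelago-level correlation beyond single islands, detection bias in the
invasive records, temporal dynamics of extirpation, or body-mass effects
(mass is generated as missing, exercising the missingness screen). Passing
tests therefore demonstrate that the machinery recovers known structure
under the stated sampling conditions — not that the fitted effect sizes in
any real dataset are correct.

## Problem sizes used in the shipped checks

Tests and the acceptance script keep the study-scale dataset at its natural
size (~1,000 islands, ~2,600 records) but scale repetition counts to desk
scale: 10–25 repeats of 10-fold cross-validation (100–250 runs) rather than
1,000, 200 replicates for the coefficient-recovery study, and 100
simulations for the selection-rule operating characteristics. These sizes
were chosen so the whole suite runs on a single core in minutes while
keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The exchangeable working correlation is a modelling convenience; the
  sandwich covariance protects inference but not efficiency.
* QICu uses the independence quasi-likelihood; alternative QIC variants
  (e.g. with V̂ from a reference model) would rank models slightly
  differently.
* In-sample MSE for order choice (as in the original protocol) favours
  larger orders slightly; cross-validated MSE is available as an option.
* The odds-ratio helper requires complete covariate profiles; it does not
  marginalize over unspecified covariates.
* Influence diagnostics use exact refits, which is O(clusters²·p) work and
  is intended for desk-scale data, not for datasets with 10⁵ clusters.
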