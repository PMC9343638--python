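# Methods

## The modeling problem

Point measurements of fluoride in wells and springs are converted to a
binary outcome — does the concentration exceed the 1.5 mg/L WHO
drinking-water guideline — and related to gridded environmental covariates
(climate, soil, topography, lithology proxies). The fitted classifier is
then applied to every raster cell to produce a hazard map (probability of
exceedance), which, combined with gridded population and country-level
untreated-groundwater usage rates, yields population-at-risk estimates.
The exceedance class is rare (~10% prevalence), which drives most of the
design below.

Binarization is strict (`> 1.5 mg/L`), applied *after* replicate
measurements of a well are averaged; averaging first and labeling once is
deliberate, since the two operations do not commute.

## Class-balanced bagging forest

Each of the `n_trees` CART trees (default 1001; `⌊√p⌋` candidate features
per split; minimum terminal node size `min_node_size`, default 1, tunable
over 1–5 by cross-validated balanced accuracy with ties to the smaller
value) is grown on an equal-count stratified bootstrap: `n_min`
observations drawn with replacement from each class, where `n_min` is the
minority count. This is the equal-expected-count realization of bagging
the minority at rate `1 − prevalence` relative to the majority, and it
makes each tree's training set balanced, so the ensemble's vote fraction
(the fraction of trees predicting exceedance, our probability output) has
0.5 as its natural operating point. Trees are sklearn
`DecisionTreeClassifier`s; `min_node_size` maps to `min_samples_leaf`.

Out-of-bag (OOB) predictions use only the trees whose bootstrap missed a
sample. Feature importance defaults to *permutation* importance — the drop
in OOB balanced accuracy when one feature column is shuffled — because it
is directly interpretable and robust to the category-count bias that
impurity-based scores carry; a mean-decrease-impurity (Gini) score is
available as a non-default alternative and no numerical equivalence with
any particular bias-corrected impurity estimator is attempted.

Backward feature elimination refits the forest, re-ranks permutation
importance each iteration (the conservative choice), removes
`max(1, ⌊0.2·p⌋)` least-important features, and continues to a single
feature. The chosen set is the smallest whose OOB balanced error is within
one standard deviation of the minimum over all iterations, with the SD
taken as the binomial approximation `√(e(1−e)/n_oob)`.

## Evaluation

"Cross-validation" is Monte-Carlo: repeated random 80/20 splits (default
100 repetitions), each stratified exactly — every class contributes
`round(fraction·n_class)` rows to the training half, so the ~0.102
exceedance proportion is maintained without binomial spread. Per
repetition: sensitivity, specificity and balanced accuracy at the 0.5
cutoff; rank-based (Mann–Whitney, midrank tie-corrected) AUC; and kappa
`κ = (acc − NIR)/(1 − NIR)` computed on ten seeded down-samples of the
majority class to minority size (so NIR = 0.5 and κ = 2·acc − 1 per
draw), averaged. The sensitivity–specificity crossover cutoff is located
on the pooled held-out predictions of all repetitions by minimizing
|sensitivity − specificity| over the unique score values, ties resolved as
the midpoint of tied thresholds. Stratified diagnostics (e.g. by depth
bin or region) reuse the same confusion metrics per stratum, flagging
strata that lack a class.

A caveat established empirically in this package and worth knowing when
interpreting crossover values at moderate sample sizes: with a few hundred
unique minority training rows, every balanced bootstrap re-uses the same
minority pool while the majority rotates through a much larger one;
fully-grown trees memorize the minority, held-out positives receive
systematically lower vote fractions, and the crossover settles below 0.5
(≈0.37–0.48 on the default strong-signal scenario at n = 5000, versus
0.59 for the balanced-posterior Bayes oracle on the same data, rising with
n). The same behaviour reproduces in an independent implementation
(R `ranger` with class-balanced `sample.fraction`), so it is a property of
balanced bagging at this scale, not of this implementation. At the very
large n of real compiled datasets the crossover sits near 0.5.

## Mapping and exposure

Raster grids are planar and axis-aligned; coarse bands (integer-multiple
cell sizes) are block-replicated onto the finest grid before prediction,
leaving values untouched. Prediction runs in row tiles (bounded memory,
bit-identical to whole-grid evaluation); any cell with nodata in a
selected band yields nodata probability and is excluded, with its
population reported as uncovered downstream.

The groundwater-consuming population is `rural_pop·rural_rate +
urban_pop·urban_rate` with country-level rates. The three estimators are:
*high* = Σ pop·p over all covered cells; *low* = Σ pop over cells with
p > 0.5 (the crossover); *hybrid* = Σ pop·p over cells with p > 0.25
(half the crossover; the cutoff is parameterized as crossover/2). Cutoff
comparisons are strict. `hybrid ≤ high` holds cellwise by construction;
all estimators are monotone in probability and population and linear in
population. Counts are kept real-valued internally.

## Synthetic study generator

The generator emulates the statistical structure of a continental
groundwater-quality compilation, not its geography:

* **Covariates** — standardized Gaussian random fields made by truncated-
  Gaussian smoothing of white noise; the smoothness parameter (kernel SD
  in cells, default 10) is the correlation length. One band is a binary
  indicator (top-quintile threshold of a smoothed field, emulating a
  lithology class); a few trailing bands are generated and stored at a
  2× coarser resolution to exercise harmonization.
* **Truth** — cellwise `p = expit(β₀ + Σ βᵢ·covᵢ)`. Informative
  coefficients default to (2.5, −2.0, 2.0), strong enough that the Bayes
  score separates the realized labels with AUC ≈ 0.97; the intercept is
  found by bisection so the spatial mean probability equals the target
  prevalence 0.102.
* **Wells** — uniform random cells, labels Bernoulli(p), concentrations
  lognormal below the guideline for negatives (median 0.3 mg/L, echoing
  the skewed bodies of real compilations) and guideline-shifted lognormal
  for positives; ~10% of wells carry 2–3 replicate rows jittered on the
  same side of the guideline; depths lognormal with median 70 m and
  log-SD 2.25, putting ≈83% in 0–600 m. Two optional in-situ columns (one
  monotone-positive, one V-shaped in the logit) exercise the association
  module.
* **Population and usage** — countries tile the grid in vertical strips;
  rural/urban populations are sums of Gaussian settlement clusters (urban
  fewer and denser); usage rates are uniform draws in [0.3, 0.9] (rural)
  and [0.1, 0.6] (urban).

Everything is a deterministic function of the scenario seed (independent
substreams per stage). What the generator does *not* emulate: geodesic
cell areas (planar equal-area cells; an optional per-cell area raster is
accepted by the areal summaries), realistic covariate semantics,
spatially clustered well placement, preferential sampling, or measurement
error — so passing tests demonstrate correctness of the chain and
recoverability of a known signal, not performance on real survey data.

## Numerical conventions

* Point-in-cell lookup uses half-open intervals in both axes; points on
  the outer boundary map to the last cell.
* Rice rule rounds up (`⌈2·n^(1/3)⌉`) and is clamped to n; equal-count
  bins place the larger bins first and break value ties stably by input
  order.
* Kendall correlation is tau-b via `scipy.stats.kendalltau`, exact
  p-value for ≤10 untied bins, normal approximation otherwise.
* Percentiles use linear interpolation between order statistics
  (numpy default); boxplot whiskers sit at the most extreme observation
  within 1.5·IQR of the hinge.
* AUC is the midrank formulation; ties contribute one half.
* Missing in-situ values are excluded per parameter; no imputation
  anywhere.

## Problem sizes used in the shipped checks

The strong-signal reference scenario is a 200×200 grid, 12 covariates
(3 informative), 5000 wells, 301 trees and 20 CV repetitions — large
enough for stable parameter recovery (CV AUC ≳ 0.95, elimination
retaining all informative covariates) while keeping a full run in tens of
seconds. The pipeline defaults (1001 trees, 100 repetitions) match the
method's standard configuration and are what a real-data run would use.

## Known limitations

* Coordinates are taken in the grid's own CRS; reprojection is a
  preprocessing responsibility.
* The crossover-below-0.5 finite-sample effect above biases the *low* and
  *hybrid* estimators' default cutoffs slightly conservative at small n.
* Balanced bagging assumes the exceedance class is the minority; at
  prevalence > 0.5 the roles simply swap.
* Country zonal statistics assume an integer country-id raster aligned
  with the hazard grid.
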