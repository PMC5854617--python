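# Methods

This note documents the models, estimators and numerical choices behind
`cascade_sdm`, the assumptions they rest on, and what the synthetic test bed
does and does not establish.

## Data model and preprocessing

A survey is a pair of site-aligned tables: a binary site×species community
matrix and a real-valued site×variable environmental matrix
(`SurveyDataset`). Preprocessing follows standard presence/absence practice:

* **Rare-species exclusion** (`filter_rare_species`, default threshold 10
  presences, strict `<`): networks cannot learn distribution patterns from a
  handful of presences, and rare-species noise degrades the whole model.
* **Exclusion by name** (`exclude_species`): species whose occurrence is not
  environment-driven (e.g. sustained by stocking programmes) are removed
  regardless of rarity.
* **Min-max normalization** to [0, 1] per variable. The default "global"
  mode scales with the whole survey's observed range, matching how a single
  survey table is normalized once before modelling. For leakage-free
  workflows, stored `(min, max)` parameters (e.g. from training folds) can
  be re-applied to new data, with out-of-range values clipped into [0, 1];
  clipping keeps sigmoid inputs in their calibrated domain at the cost of
  saturating extrapolated sites.
* **Stream velocity** is a semi-quantitative 0–5 score. The printed field
  classes leave small gaps (6–7, 30–35, 50–55 cm/s); `velocity_to_score`
  closes them by taking each class's upper bound as inclusive
  (<5→0, ≤6→1, ≤30→2, ≤50→3, ≤100→4, >100→5), making the mapping total.

Repeated seasonal visits to a site are ordinary rows; no site-level blocking
is applied, and geographic coordinates are deliberately out of scope (their
use invites spatial-autocorrelation artefacts).

## Tetrachoric correlation

Candidate co-predictors are ranked by the tetrachoric correlation between
their occurrence vector and the target's: the correlation ρ of a latent
standard bivariate normal whose dichotomization at thresholds (h, k) would
produce the observed 2×2 table. The estimator is the conventional two-step
maximum-likelihood one: thresholds are fixed from the margins
(h = Φ⁻¹(P(absent))), then the multinomial likelihood of the four cells is
maximized over ρ ∈ [−0.9999, 0.9999] (bounded scalar minimization, xatol
1e−8). Rectangle probabilities use Owen's T-function identity for the
bivariate normal CDF (`scipy.special.owens_t`), exact to ~1e−15 against
direct numerical integration; thresholds within 1e−10 of zero are nudged off
zero to keep the T-function slopes finite. Tables with a zero cell receive
the standard +0.5 continuity correction (`corrected=True`); a zero *margin*
(species always or never present) is an error, reported as a null entry by
`correlation_ranking` rather than silently dropped.

Assumption to keep in mind: the latent-normal model is a convenient
abstraction. Under the generator below, true liabilities are
logistic-normal, so "realized" tetrachoric values differ slightly from the
latent input correlations; recovery tests therefore use exactly
dichotomized bivariate-normal draws.

## Networks

One architecture everywhere: inputs → single hidden layer → one output,
logistic activations on hidden and output layers, bias units on both.
Training minimizes mean binary cross-entropy (the Bernoulli likelihood for a
logistic output; squared error available) plus `weight_decay · Σθ²`, by
full-batch L-BFGS-B with analytic backprop gradients (`ftol` = configured
tolerance, default 1e−8; up to 2000 iterations). Weights initialize uniform
on ±`init_range` (default 0.5); `restarts` seeded initializations (default
5) are run and the best final loss kept. Cross-entropy is computed through
the logit (`log(1+e^z) − yz`), so saturated units cannot produce non-finite
losses. Everything is deterministic given the seed: restart seeds, fold
seeds and sub-model seeds all derive from one master seed through
`numpy.random.SeedSequence`.

The hidden-layer size is selected by `sweep_hidden_sizes` over 1–15 units,
scored by median cross-validated kappa, ties resolved toward fewer units.

## Validation

* **Cutoff**: network outputs are binarized at the threshold maximizing
  Youden's J on the ROC curve, with candidate cutoffs at midpoints between
  adjacent distinct scores and exact ties resolved toward the candidate
  nearest the neutral 0.5. Scores equal to the cutoff count as presence.
  With fewer than two distinct scores the cutoff falls back to 0.5.
* **Kappa**: computed exactly from the confusion matrix; the confidence
  interval is k ± z·SE with the Fleiss–Cohen–Everitt large-sample standard
  error, clipped to [−1, 1]. An alternative "folds" interval
  (mean ± t·sd/√k over fold kappas) is selectable, since CI provenance
  conventions differ between studies. Landis–Koch bands use inclusive upper
  bounds (0.8 is still "substantial"); the coarser field aliases "good" /
  "very good" for the top two bands are available via `alias=True`.
* **Cross-validation**: stratified k-fold (default 5), folds dealt
  round-robin after a seeded within-class shuffle, so per-fold class counts
  are within one of proportional. Whether folds should be stratified at all
  is a convention choice; stratification is the default here and flagged as
  an assumption. Per fold, the cutoff is chosen on the held-out fold's
  scores (`cutoff_mode="test"`), reproducing the common
  cutoff-on-the-test-set practice; this leaks the test labels into one
  scalar and flatters kappa slightly, so `cutoff_mode="train"` is provided
  and recommended for new work. A fold whose kappa denominator vanishes
  (chance agreement = n) is scored 0 (chance level). The reported matrix is
  the fold whose kappa is closest to the median (ties toward the earlier
  fold).

## The cascade, and where information can leak

`CascadeClassifier.fit(X, y, copredictors=C)` trains one environment-only
sub-network per co-predictor and a target network on `[X, P]`. Choices:

* **Composition** — `"retrain"` (default) trains a fresh target network on
  sub-model *probabilities*; `"reuse"` keeps the screening-style network
  trained on *observed* occurrences and swaps in sub-model probabilities at
  prediction time. The two coincide exactly when sub-model outputs equal the
  observed occurrences (verified by test). Probabilities are passed
  continuously by default; `copredictor_inputs="binary"` binarizes them at
  each sub-model's ROC cutoff for ablation.
* **Training-time inputs** — `oof="out_of_fold"` (default) computes the
  probabilities fed to the target network during training by seeded k-fold
  refits of each sub-model, so the target network never sees in-sample
  sub-model outputs; `"in_sample"` uses the final sub-models directly.
* **Evaluation scope** — `compare_cascade_benefit(submodel_scope=...)`
  controls what the cascade's cross-validation measures.
  `"survey"` applies the four-step procedure literally: sub-models are
  trained once on the whole survey (observed co-predictor occurrences exist
  at every training site) before the target model is cross-validated. Their
  predictions at held-out sites then come from networks that saw those
  sites' occurrences during training; this partial memorization is
  *precisely* how predicted co-predictor probabilities convey biotic
  information beyond the measured environment, and it is not available to a
  model deployed on genuinely new sites. `"fold"` refits sub-models inside
  each training fold; in that fully leakage-free regime the cascade's
  held-out inputs are pure functions of the same environment the baseline
  sees, and its advantage reduces to sample-efficiency (typically small).
  Anyone using this package on real data should treat the `"survey"` kappa
  as an upper bound and report the `"fold"` kappa alongside it.

`predict_cascade` consumes a DataFrame of environmental columns matched by
name; species columns are never read (bit-identical predictions with or
without them — a tested contract), and a missing environmental column is a
named schema error.

## Variable importance

* **Profile (Lek)**: each input sweeps 50 evenly spaced points across [0, 1]
  while the others sit at one of five levels — their own min/Q1/median/Q3/max
  (`"quartiles"`, default) or the fixed grid {0, 0.25, 0.5, 0.75, 1}
  (`"fixed_grid"`). Both conventions circulate; both are shipped. For a
  cascade, sub-model probability inputs are profiled like any variable.
* **Perturbation**: uniform white noise on [−0.3, 0.3] is added to one input
  at a time (perturbed values clipped back to [0, 1], the normalized input
  domain; unclipped mode available), and importance is the percent increase
  in mean squared error. The reference is the observed occurrences by
  default, or the unperturbed predictions (`error_reference="predictions"`),
  a distinction that matters for poorly fitting models. A single noise draw
  is high-variance, so 100 seeded repetitions are averaged, every variable
  receiving the *same* noise bank — importances are paired and exactly
  permutation-equivariant.
* **Connection weights (Olden)**: contribution_i = Σ_h w_ih·v_h over hidden
  neurons, biases excluded (the method concerns input→hidden→output paths);
  the sign gives the direction of association.

## The virtual community

`simulate_community` draws per-site latent habitat axes (standard normal),
builds environmental variables as noisy linear mixes of *some* axes rescaled
to field-realistic ranges, and draws each species independently from a
logistic model on the latents, optionally plus a biotic dependence on
another species' realized occurrence (dependence links must be acyclic).

The canned scenario (`make_reference_scenario`) is shaped like a regional
stream-fish survey: 264 sites, 20 environmental variables with realistic
ranges (elevation 13–1785 m, pH 5.63–9.33, a 0–5 velocity score, ...), 23
species. Three latent axes: a main river gradient and a secondary axis that
the environment observes noisily (per-variable noise sd 1.25–2.5 against
loadings ≤0.9 — each variable is a weak indicator, so recovering the axes
requires pooling many), and a **hidden habitat factor** with no
environmental loading at all. The target (intermediate prevalence, ~0.35–0.42
across seeds) loads (1.8, 0, 2.2) on these axes; the two co-predictors load
much more sharply ((6.0, 0, 3.5) and (5.5, 0.3, 3.2)), making them easier to
model and tetrachorically correlated ~0.75–0.78 with the target; the
community also contains strongly negatively correlated upland species, two
biotic-dependence links, and one pure-noise species (|r| < 0.05). Analysis
settings for this scenario (`reference_train_configs`) use small decayed
target networks (4 hidden units, decay 1e−3) and tighter sub-models (6
hidden units, decay 3e−4), mirroring per-model tuning; restarts are limited
to 2 and iterations to 200–300, which L-BFGS comfortably exhausts at these
problem sizes and keeps a full 20-replicate ordering experiment around ten
seconds.

What passing the ordering experiment shows: under exactly the assumed
structure — shared latents partially hidden from the environment,
conditionally independent Bernoulli occurrences, monotone logistic
responses — the observed-co-predictor model ≥ cascade ≥ baseline ordering
holds in ≥18 of 20 seeded replicates, with the cascade strictly above the
baseline. What it does not show: robustness to spatial autocorrelation,
observer error in the community matrix, abundance effects, non-monotone
responses, or environmental variables correlated with the "hidden" factor —
none of which the generator emulates.

## Numerical details and edge cases

* Tetrachoric optimizer: bounded Brent on [−0.9999, 0.9999]; cell
  probabilities clipped at 1e−300 before logs.
* A balanced independent table estimates r = 0 to ~1e−8; a perfect-agreement
  table (50/0/0/50) estimates r ≈ 0.9995 after correction, matching a
  brute-force grid maximization of the same likelihood to <5e−3.
* CSV round-trips are bit-exact: floats are written with `%.17g` and parsed
  with pandas' `round_trip` converter.
* Degenerate inputs raise typed errors (`DegenerateError`,
  `StratificationError`, `SchemaError`, `CompositionError`) naming the
  offending variable, species or column.
* All stochastic stages accept an integer seed; identical seeds give
  bit-identical models, folds, simulations and CSV outputs.

## Known limitations

* Single-hidden-layer sigmoid networks only; no mini-batch training, no
  multi-label targets, no recursive cascades (sub-models of sub-models).
* The tetrachoric module has no polychoric generalization and reports no
  standard errors for r (it is used only to order candidates).
* The asymptotic kappa CI is a large-sample approximation; at fold sizes
  near 50 it is indicative rather than exact.
* The screening step cross-validates one candidate at a time; interactions
  among candidates are only captured in the final k-co-predictor model.
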