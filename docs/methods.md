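# Methods

## Pair features

For sample *k* with log2 expression vector *g·k*, the feature of the
unordered pair (i, j), stored in canonical lexicographic orientation, is
the sign indicator `r_k = I(g_ik − g_jk)` with `I(x) = +1` for `x > 0`
and `−1` for `x ≤ 0`.  Exact ties map to −1: ties have measure zero on
continuous expression data but are common in small fixtures, and a fixed
convention keeps results reproducible.  The orientation convention is
irrelevant to the screen (Fisher's test is symmetric under flipping the
+1/−1 encoding) and is absorbed by model coefficients; it is fixed so
serialized models are portable.

Candidate pairs are the union, over all gene sets in a GMT collection, of
all unordered pairs of set members that are measured in every cohort
being analysed (the cross-cohort common-gene intersection).  Pairs are
deduplicated and sorted lexicographically, so the candidate list is
independent of set iteration order.  Unrestricted all-vs-all pairing is
deliberately not the default: n(n−1)/2 grows to ~5.8×10⁷ pairs at the
~10⁴ genes typically detected in common, and within-pathway pairs keep
the candidates interpretable.

Cohorts are pooled by computing pair features *within* each cohort and
concatenating columns; no expression value is ever compared across
cohorts.  This is the operation that makes the pipeline robust to batch
effects: any per-sample strictly increasing distortion and any
cohort-wide additive shift leave the feature matrix bit-identical
(property-tested).  Per-(cohort, gene) shifts do change individual
features, but with case/control balance within cohorts they do not create
differential signal; the screen's false-positive tests cover this.

## Screening

Each pair's +1/−1 state is cross-tabulated against the binary label and
tested with the two-sided Fisher exact test under the
minimum-likelihood convention (sum of hypergeometric probabilities of
tables, with the observed margins, no more probable than the observed
table).  The implementation delegates to `scipy.stats.fisher_exact`; an
independent brute-force enumeration oracle in the test suite verifies
agreement to better than 10⁻¹² relative error for every 2×2 table with
total ≤ 40.  Family-wise error is controlled with Bonferroni over the
pairs actually tested (not the notional all-vs-all universe), and
significance means adjusted p **strictly below** the threshold; the
default threshold 10⁻²⁰ reflects the extreme contrasts genuinely
reversed pairs produce at a few hundred samples.  Benjamini–Hochberg is
deliberately not used at this stage — Bonferroni is the procedure the
protocol names.

## Diagnostic model

Feature selection is stability selection over `n_repeats = 100`
stratified 80/20 splits.  The splitter allocates classes by largest
remainder so the train part has exactly `floor(0.8·n)` samples (474
samples split 379/95) with at least one sample of each class on both
sides.  Each repeat fits an L1-penalized logistic regression on the
train part — penalty strength chosen over a log grid (10⁻²…10²,
9 points) by stratified cross-validated AUC with the
**one-standard-error rule** (smallest C within one SE of the best mean
AUC) — and the repeat's model is scored on the held-out 20%.  A pair's
occurrence counter increments only when the pair's coefficient is
non-zero *and* the repeat's held-out AUC exceeds 0.8, so unstable splits
do not vote.  The 1-SE rule matters: at the CV-optimal penalty, noise
pairs accumulated occurrence counts as high as ~70/100 in planted
simulations; with 1-SE sparsity, planted pairs sit at ≥ 90 and the
largest null near 20, giving the wide margin the occurrence threshold
relies on.

Candidates are pairs with occurrence strictly greater than the
threshold (default 50 of 100).  The threshold can be tuned over the grid
{10, 20, …, 100} by refitting the final model per grid value and scoring
a disjoint evaluation set; ties resolve to the smaller threshold.  The
final model is an L1 logistic regression restricted to the candidates
(10-fold CV, same 1-SE rule), with zero-coefficient pairs pruned.
Random-forest (500 trees) and gradient-boosted-tree (300 rounds, depth 3)
baselines are fit with fixed seeds on the same ±1 features purely for the
method comparison report; AUC is the Mann–Whitney statistic with ties
counted 1/2 throughout.

## Prognostic model

Candidate pairs (typically the diagnostic model's pairs) are filtered by
a univariate Cox proportional-hazards fit of the single ±1 feature
(lifelines; Wald p < 0.05, two-sided, unadjusted — no multiplicity
correction at this stage, mirroring common practice).  Pairs with a
constant feature or fewer than two events are skipped with a log entry.

The multivariable fit is an L1-penalized Cox regression
(scikit-survival's Coxnet path, 50 alphas, `alpha_min_ratio = 0.01`).
The penalty is chosen by the Verweij–van Houwelingen cross-validated
partial likelihood — for each fold, the difference between the full-data
and training-fold Breslow partial log-likelihoods evaluated at the fold's
coefficients — again with the one-SE rule (sparsest alpha within one
fold-SE of the optimum).  The Breslow partial log-likelihood of a fixed
coefficient vector is computed in-package (a short log-cumsum-exp over
risk sets); no installed routine exposes held-out partial likelihood at a
fixed beta.  The CV optimum alone retained most null pairs in planted
simulations; the 1-SE rule recovers the planted support exactly.

The risk score is the bare linear predictor `s_k = Σ β_p r_pk` (no
baseline hazard — only the ranking matters downstream).  Patients are
split at the **median score, ties going to the high-risk group**
(deterministic, and ±1 features make score ties likely); by default each
cohort uses its own median.  Groups are compared with Kaplan–Meier
product-limit curves and the two-group log-rank test (lifelines).

Discrimination at horizon *t* uses the cumulative-cases / dynamic-controls
AUC: cases are subjects with an observed event by *t*, controls those
still event-free beyond *t*, weighted by inverse probability of censoring
(cases by 1/Ĝ(Tᵢ⁻), controls by 1/Ĝ(t), Ĝ the Kaplan–Meier estimate of
the censoring distribution with left-limit evaluation).  Ties in the
score count 1/2.  With zero censoring all weights are 1 and the estimator
reduces *exactly* (to 10⁻¹⁰, tested) to the plain AUC on the dichotomized
outcome — the identity that pins down the convention.

## Enrichment

Over-representation of a gene list (for pair models: the union of both
genes of each pair) against a GMT collection, by the upper tail of the
hypergeometric distribution.  The universe is the set of genes measured
in the analysis, not the genome — the only defensible default when no
universe is prescribed.  Default adjustment is Benjamini–Hochberg with
Bonferroni available; only sets intersecting the universe are tested and
corrected for.

## Synthetic studies

The generator emulates a multi-cohort case/control compendium with
survival follow-up.  Per cohort: baseline gene means μ_g ~ N(8, 2) in
log2 units (shared across cohorts), per-sample noise N(μ_g, 1),
per-(cohort, gene) additive batch offsets N(0, `batch_shift_sd`), planted
pair reversals, and optional per-sample distortions (affine `a·x + b`,
a ~ U(0.5, 2), b ~ U(−2, 2); or a strictly increasing piecewise-linear
map with 5 random interior knots).  A planted pair (a, b) is reversed per
sample: with the group-specific probability, g_a is set above g_b by a
margin δ ~ U(0.5, 1.5) around the pair's current mid-point, otherwise
below.  The margin scale is the difficulty knob: ~1 log2 unit survives
unit noise most of the time without being trivial.

Two ordering decisions matter and are deliberate:

* **Reversals are imposed after the batch offsets.**  An additive
  per-gene cohort offset shifts g_a − g_b by a constant ~N(0, 2·sd²) per
  cohort; at sd = 2 that constant usually exceeds the reversal margin and
  would erase a previously imposed contrast in most cohorts.  Imposing
  reversals last makes the configured rates the rates actually realized
  in the observable data — which is what "ground truth" must mean for a
  recovery benchmark.
* **Planted pairs are spread across pathways** (balanced packing of the
  planted connected components, which must each fit inside one pathway).
  Planting moves gene values, so a cross-pair between two planted pairs
  carries genuine secondary differential signal; keeping planted pairs in
  different pathways keeps such cross-pairs out of the within-pathway
  candidate set, so "null candidate pairs" are truly null.

Survival for cases is exponential with rate
`baseline_rate · exp(Σ β_p r_p)` on the realized pair features, censored
at U(0, `censor_time_max`) (or uncensored when the bound is `None`).
Randomness flows from one seed through named substreams (means, noise,
batch, planted, distortion, survival), so toggling one stage never shifts
another's draws and regeneration is bit-identical.

What the generator does *not* emulate: probe-level measurement,
gene–gene correlation beyond the planted pairs, heavy-tailed or
count-based noise, non-proportional hazards, and informative censoring.
Passing recovery tests therefore demonstrate correctness of the
machinery under the stated generative model, not performance on real
cohorts.

## Problem sizes and defaults

Recovery benchmarks use 3 cohorts × (50 cases + 50 controls) with 120
genes in 6 pathways (1140 candidate pairs) for the diagnostic chain, and
a single 400-case cohort with 12 variable pairs (6 with β = ±1, 6 null)
for the prognostic chain — sizes at which every stage's behaviour is
unambiguous while a full multi-seed run stays in the tens of seconds.
The bundled `small` preset (3 × 60 samples, 60 genes, 5 planted pairs,
2 survival pairs with β = ±2) exercises the complete pipeline, including
threshold auto-tuning and enrichment, in well under a minute.

Stage defaults: screen threshold 10⁻²⁰ (adjusted p), 100 stability
repeats, occurrence grid {10, …, 100} with threshold 50 or auto,
10 CV folds for both final fits, survival horizons {1, 3, 5} in the input
time unit.

## Known limitations

* Expression input is a complete gene-level matrix; missing values are a
  hard error and probe collapsing is out of scope.
* The Fisher screen assumes independent samples; related samples or
  duplicated patients would inflate significance.
* The occurrence gate uses split-level model AUC (> 0.8), not per-pair
  AUC: a single ±1 feature rarely reaches 0.8 alone, so a per-pair gate
  would be vacuous.
* The time-dependent AUC requires at least one event by, and one subject
  at risk beyond, each horizon; the pipeline records `null` for horizons
  where the cohort cannot support the estimate.
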