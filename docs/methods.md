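# Methods

## Data model

A patient record is an ordered series of bedside pupil readings on a nominal
2-hour grid (hours since ICU admission; strictly increasing; all ≤ the
discharge hour), plus the hour sedation ended and the 6-month GOSE. Pupil
size takes 5 categories with ISOCHORIC the unique normal state;
photo-reactivity takes 4 with BILATERAL_PRESENT normal. Outcome is the GOSE
dichotomy (favorable iff GOSE > 4); the record validates label/GOSE
consistency on construction. Whether real bedside charts are exactly
2-hourly is unknowable from published material; the grid is an assumption
and the sampling interval is configurable.

## Indices

For the observations inside a half-open window `[start, end)`:

- jump rate = (# consecutive-observation changes) / N. The per-measurement
  denominator N follows the index's printed definition even though the
  per-transition N−1 form is the statistically conventional one; the latter
  is available via `denominator="per_transition"`. A jump rate needs N ≥ 2;
  an occupancy needs N ≥ 1; otherwise the index is NaN, never 0.
- occupancy percentage = fraction of observations in the normal state.

Conventions: an observation exactly on a boundary belongs to the later
window; missing grid points contribute to neither numerator nor denominator
(complete-case within window); a change across a gap counts as at most one
change (it is a single consecutive-observation pair). "Day k" is
`[24k, 24(k+1))` h; the cumulative window for ND is `[0, 24·(ND+1))`, so
ND = 0 uses the first full day and a "day 0" model is estimable. The PRE
window is `[0, sedation_stop)`; POST is `[sedation_stop, discharge]`
(inclusive of a reading exactly at discharge). Both per-day and
running-cumulative time courses are provided, since published per-patient
trajectories could be either.

## Synthetic cohorts

No patient-level series are published for the reference cohort, so every
stage is exercised on synthetic cohorts. Each patient's PS and PR series are
independent first-order Markov chains sampled on the grid, with a single
hard regime switch at sedation stop (the simplest mechanism that produces
the observed stabilization; no taper). Stay and sedation lengths are
truncated-normal draws (defaults 17 ± 9 and 9 ± 6 days — the reference
cohort's printed scales), truncated below at 1 day, sedation clipped to the
stay, both rounded to the grid; the default 14 favorable + 6 unfavorable
split matches the analyzed reference cohort. At the 2-h cadence this yields
≈ 215 observations per patient on average, the same order as the ≈ 191
reported for the reference data. GOSE is drawn uniformly from {5..8}
(favorable) or {1..4} (unfavorable); only the dichotomy is consumed
downstream. Optional missingness drops grid points independently (the first
two are always kept so a record stays valid).

Default transition matrices encode the published qualitative pattern, chosen
once as follows and not fit to any data:

- favorable: isochoric/reactive self-transitions 0.96–0.97 in both regimes
  (stationary normal occupancy ≈ 0.94), brief abnormal excursions;
- unfavorable, pupil size: isochoric self-transition 0.70 under sedation
  (stationary isochoria ≈ 0.5, jump rate ≈ 0.4); after sedation all size
  states become quasi-absorbing (self-transitions 0.95–0.975) with the
  stationary isochoria held at its sedation-era value — jumping collapses
  while mean occupancy does not move, i.e. stabilization toward pathological
  values without a period main effect in isochoria;
- unfavorable, photo-reactivity: mildly reduced presence under sedation
  (≈ 0.82) declining after it ends (≈ 0.6), making reactivity the weaker
  between-group discriminator, with a period-by-outcome interaction.

Across 100 default cohorts this reproduces the reference effect pattern:
the between-group effect on PS-isochoria-percentage is detected in 100/100
cohorts; PS-jump-rate shows all three effects essentially always;
PS-isochoria shows no period effect or interaction beyond near-nominal
rates; PR-presence shows a between-group effect (~0.99) and an interaction
(~0.68) but only a weak period main effect — the one element of the
reference pattern the generator reproduces least sharply. What passing
tests show is therefore that the *pipeline* behaves correctly under
dynamics with this structure; the generator does not model drug
pharmacokinetics, ICP, measurement error, inter-observer disagreement, or
PS–PR cross-dependence (the chains are sampled independently; their
empirical correlation is not a modelling target).

## Group inference

The 2×2 mixed ANOVA (between: outcome; within: period) is computed with
`pingouin.mixed_anova` on listwise-complete patients (a patient whose POST
window supports no value is excluded from that index's ANOVA); groups are
unbalanced (14 vs 6) and the implementation was verified against an
independent cell-means sums-of-squares decomposition and against the
identity F_between = t² on subject means. With zero error variance the F
ratios are reported as NaN with a warning. Six post-hoc contrasts are
computed per index — between groups at PRE and at POST (pooled-variance t),
within each group PRE vs POST (paired t), and the two marginal contrasts
(group main on patient means, period main paired over all patients) — each
raw p multiplied by 6 and capped at 1.

Covariate tests reproducible from printed group summaries use the
pooled-variance (Student) two-sample t — the dialect that reproduces the
reference cohort's age statistic exactly — Yates-corrected chi-square for
2×2 count tables (reproduces the printed tSAH/EDH/IVH/NS/INM statistics)
and plain Pearson chi-square for r×c tables (reproduces the Marshall-score
statistic, df = 3). The printed gender and contusion chi-squares and the
sedation/ICU-stay t statistics are not reproducible from the printed
summaries under any standard convention (they were presumably computed on
unrounded raw data, or are typos) and are excluded.

## Prognosis

Outcome is coded favorable = 1, so occupancy indices correlate positively
and jump rates negatively. Point-biserial screening is the Pearson
correlation against the 0/1 coding with the t-transform p (df = n−2);
significance marking in the sweep is two-sided p < 0.05, uncorrected.

Logistic models are fit by maximum likelihood (statsmodels) with an
intercept. With 20 patients and strong predictors, complete or
quasi-complete separation is the norm; a fit is flagged as separated on
non-convergence, an MLE failure, or any |coefficient| > 30, and is then
refit with Firth's Jeffreys-prior penalty (hand-implemented damped Newton on
the adjusted score; finite estimates exist under complete separation). For a
separated model the LR p-value and BIC are computed from the penalized
log-likelihoods (null model penalized likewise) so the score grid stays
finite; the separation flag is always reported. "Model significance" is the
likelihood-ratio test against the intercept-only model (χ², df = number of
predictors); a Wald test would be meaningless under separation.
`BIC = (k+1)·ln n − 2·ln L`. LOOCV accuracy counts a held-out patient
correct when the predicted probability is strictly on the correct side of
0.5; folds whose training set is single-class predict the training majority.
Because the Firth penalty differs across model dimensions, the penalized
likelihood is not monotone under predictor nesting; the score grid therefore
also records a numerically maximized *unpenalized* log-likelihood (bounded
quasi-Newton approximation of the supremum), which is the quantity checked
for nested-deviance monotonicity.

The sweep scores all 2⁴−1 = 15 predictor subsets at each ND 0..10, skipping
an ND with fewer than 3 complete patients in either class; per-ND best
models under each criterion break ties toward the smaller subset, then
lexicographically. ROC curves use the fitted probabilities of the
single-predictor model in-sample (AUC is monotone-invariant, hence identical
to ranking by the raw index up to slope sign); a LOOCV mode scores held-out
probabilities instead. AUC is the trapezoidal area, equal to the
Mann–Whitney pairwise probability with ties counting ½; an all-tied
predictor is reported as AUC 0.5. LOOCV accuracy is reported as a percentage
with one decimal and never rounded per fold.

## Problem sizes and numerics

Monte-Carlo checks use 100 cohorts of 14+6 patients for detection/selection
rates and 25 for AUC/LOOCV summaries; the type-I-error check uses 400
replicates of a single noise predictor. Row-stochasticity is enforced to
1e-9; nesting monotonicity is asserted to 1e-6 (optimizer tolerance); the
exact-reproduction tests match printed statistics to half a unit in the last
printed digit, except where the printed inputs are themselves rounded (the
age t/p), where one unit in the last place is allowed. Firth Newton steps
are damped to a maximum coordinate step of 5 for stability on tiny samples.

## Known limitations

The generator's cohorts are cleaner than real bedside data: no observer
noise, no informative missingness, no within-group heterogeneity of
dynamics (all patients in a group share one matrix pair), and discrimination
is consequently near-ceiling (AUC ≈ 1 by day 3–5, LOOCV accuracy typically
100%). The reference cohort's headline inferential values (its exact F and
post-hoc t statistics, BIC = 13.56, accuracy 95) depend on the unpublished
patient-level series and are reproduced here only qualitatively (same
selection winner, same effect pattern, same order of magnitude of BIC).
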