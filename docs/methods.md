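# Methods

## The synthetic cohort

The generator emulates a multi-centre genetic-FTD observational study. Each
subject belongs to a (genotype × clinical status) cell; default cell sizes
are 298 non-carrier controls, 129/77 presymptomatic/symptomatic C9orf72,
137/45 GRN, and 50/27 MAPT carriers (763 subjects). Ages are drawn per
status (controls 47.3 ± 13.6 y, presymptomatic ≈ 46 ± 12 y, symptomatic
63 ± 8.5 y), sex is male with probability 0.42, and education is
14.4 ± 3.2 y (12.5 ± 3.5 y for symptomatic carriers).

**Disease mechanism.** Each subject carries a latent stage s ∈ [0, 1]:
controls sit exactly at 0, presymptomatic carriers are Uniform(0, 0.5), and
symptomatic carriers Uniform(0.4, 1) — the overlap reflects that clinical
conversion is not a sharp point on the biomarker cascade. Biomarkers become
abnormal in a fixed ground-truth order; the event at position j of K fires
once s > j/(K+1). The default cascade puts the three WMH markers first, then
ventricles and NfL, then temporal and frontal grey matter, cerebellum, and
GFAP, with the six subcortical volumes appended afterwards for the
longitudinal analysis.

**Measurement model.** Lesion and fluid markers (WMH, ventricles, NfL,
GFAP) are log-normal: normal/abnormal parameters are means and sds of
log10 values, and stored values are back-transformed so the table looks like
raw measurements (WMH in mm³, NfL/GFAP in pg/mL, ventricles as an ICV
fraction). Grey-matter volumes are Gaussian ICV-normalised fractions.
Abnormal components sit 2.3–2.6 pooled-sds from normal in the declared
direction — clearly bimodal but overlapping mixtures, with the log10
total-WMH control mean (3.45) and the symptomatic-carrier shift chosen to be
of the magnitude seen in published lesion-volume tables. Age and sex enter
as additive effects on the analysis scale (e.g. +0.010 log10 WMH per year),
so the symptomatic group's higher age produces a genuine confound that the
normative and DEBM adjustments must remove. WMH events fire only in GRN
carriers (the genotype specificity the group comparison is designed to
detect); atrophy and fluid events fire in carriers of any genotype. NfL is
missing completely at random in 21% of subjects and GFAP in 38%, matching
typical fluid-biomarker availability; clinical scores are missing in 10%.

Left/right lobar WMH columns split the corresponding summed marker with a
Beta(40, 40) share; parietal and occipital lobes are event-free
log-normals. The additive constraint "total = sum of lobes" is not
enforced — no analysis consumes it. Clinical scores (CDR-FTLD sum-of-boxes,
MMSE, TMT-B, Boston Naming, Digit Symbol, Verbal Fluency) are noisy
monotone transforms of the latent stage with the clinically expected signs.

**Longitudinal extension.** 70 presymptomatic and 13 symptomatic GRN
carriers (83 subjects) receive 3 visits 1.1 years apart. For each
trajectory marker the per-subject annual slope in z-units is
`base_slope + Σ coupling × z(baseline predictor) + N(0, noise_sd)` with
defaults: subcortical drift −0.04 z/y, WMH growth +0.06 z/y, couplings
total-WMH → {amygdala, hippocampus, cingulate} = −0.3 and all others
(including every reverse subcortical → WMH coupling) zero, slope noise
0.10 z/y, and visit-level measurement noise 0.05 z. Standardisation
constants are the empirical mean/sd of each marker's transformed baseline
over the selected subjects.

What the generator does *not* emulate: scanner/site effects, informative
missingness, measurement drift, genotype-specific cascade orderings, or
mutation subtypes. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative assumptions, not
robustness to those real-data complications.

## Normative WMH statistics

The normative model is ordinary least squares of log10 WMH volume on age
and a binary male contrast, fitted only on controls with complete
demographics; a subject's adjusted WMH is their observed log10 volume minus
the model prediction, so control residuals average to zero by construction.
If the controls contain a single sex the contrast is dropped (coefficient
0); constant age with a single sex raises a rank-deficiency error naming
the collinear terms. Records missing age or sex are excluded and counted.

Group comparisons are nonparametric: tie-corrected Kruskal–Wallis H
(defined as 0 when all pooled values are tied), Dunn's pairwise z on pooled
ranks with the standard tie correction and two-sided normal p-values, and
Cliff's delta as the effect size. The Bonferroni family is every pairwise
contrast across all regions of one analysis table (with 7 groups and 9
regions: 21 × 9 = 189 tests); the family size is logged and attached to
every row.

## The event-based model

An event is one biomarker's transition from its normal to its abnormal
distribution; with K biomarkers the disease has K ordered events. The model
is discriminative: it never estimates a subject's stage to estimate the
ordering, only per-biomarker abnormality posteriors.

1. **Transform and adjust.** Skewed markers (WMH, ventricles, NfL, GFAP)
   are log10-transformed; every marker is residualised on age and sex with
   control-fitted OLS. Missingness is preserved; nothing is imputed.
2. **Screen.** Two-sided Mann–Whitney U, symptomatic vs control, per
   biomarker; significance at p < 0.05 is required for admission.
3. **Mixture fit.** A constrained two-component EM per biomarker on all
   non-missing values: the normal component is initialised at the control
   mean/sd and the abnormal component from the symptomatic values beyond one
   control sd in the declared direction (initialising from the half-tail
   lets EM absorb normal-state carrier values into a barely-shifted
   "abnormal" component — a local optimum, not the separated mode).
   Each diagnosis label (control / presymptomatic / symptomatic) has its own
   abnormal mixing fraction, the control fraction capped at 0.10 to prevent
   label switching; component sds are floored at 0.05 × pooled sd. EM stops
   when no parameter moves by more than 1e-4 (late events with a handful of
   abnormal observations sit on nearly flat likelihood ridges, so tighter
   tolerances only buy iterations, not information) and errors out after
   500 iterations carrying the last state. Fit quality is the mean squared
   error between the fitted mixture density and a 50-bin empirical density
   of the standardised values; admission requires MSE ≤ 0.01. The
   threshold sits about four times above the sampling-noise floor of such a
   histogram at n ≈ 500 (mean density / (n × bin width) ≈ 2e-3, attained
   even when the fitted mixture is exactly the generating density), so it
   rejects gross misfits without rejecting correct fits. A fit whose means
   are not separated in the declared direction is kept but not admitted.
4. **Posteriors.** P(abnormal | x) uses equal component priors — a pure
   likelihood ratio, independent of cohort composition; the estimated
   mixing fractions serve only the density-fit MSE.
5. **Central ordering.** Each subject's observed biomarkers are ranked by
   descending posterior (ties broken alphabetically). The central ordering σ
   minimises the summed probability-weighted Kendall distance: for every
   subject and observed pair discordant between σ and the subject's ranking,
   the cost grows by |P_ik − P_il|, so near-tied posteriors are
   uninformative and the weights reduce to plain Kendall distance for binary
   posteriors. The cost decomposes over ordered pairs
   (W[k, l] = Σ_i max(0, P_il − P_ik)), making it a linear ordering
   problem: exhaustive search over all K! permutations for K ≤ 7, otherwise
   greedy best-improvement pairwise swaps from the descending-column-mean
   initialisation with 10 seeded random restarts. On planted 6-biomarker
   instances the greedy solution attains the exhaustive minimum in ≈ 100%
   of cases.
6. **Uncertainty.** 100 bootstrap replicates, resampled with replacement
   within each diagnosis label (so every replicate preserves the
   three-diagnosis design), mixtures refit per replicate over the fixed
   admitted set; a replicate whose refit fails is redrawn (at most 10
   times). The position counts form the positional-variance diagram; each
   row and column sums to the replicate count by construction.
7. **Staging.** The discrete stage k ∈ {0..K} maximises
   Σ_{j≤k} log P_σ(j) + Σ_{j>k} log(1 − P_σ(j)) over observed biomarkers
   (posteriors clipped to [1e-6, 1 − 1e-6]; ties go to the smallest k); the
   continuous stage is the mean observed posterior. Validation: stratified
   10-fold cross-validated AUC of the continuous stage for symptomatic vs
   control, and pairwise-complete Spearman correlations with the clinical
   scores.

**Identifiability at this cohort composition.** With 45 symptomatic
carriers uniform over stages 0.4–1, only ≈ 7 subjects fall between
consecutive late event thresholds, so the order of late events is weakly
identified: the adjacent-swap decision statistic Σ_i (P_ik − P_il) has a
signal-to-noise ratio below 1 for the last event pairs even when posteriors
are computed from the true generative parameters. Exact recovery of all
nine positions at 2-sd component separation is therefore rare (the
validation battery reports the observed rate and the Kendall-tau spread
rather than asserting perfection), while the early WMH block is recovered
essentially always and the bootstrap diagram shows exactly the
early-tight / late-diffuse morphology one expects. Stage–latent-stage
correlation is reported over mutation carriers; over the full cohort the
statistic is structurally capped near 0.72 because controls form a point
mass at stage 0 (62% of subjects tied), a ceiling that applies to any
estimator.

## Cross-lagged longitudinal models

All biomarkers are z-scored with constants computed over the analysis
dataset at baseline (WMH and NfL log10-transformed first); follow-up values
use the same constants, so rates are in baseline-sd units per year. The
per-subject rate is the OLS slope of the z-scored marker against visit time
over all visits (a difference quotient for two visits); subjects with fewer
than two observed visits are excluded for that marker only. Each directed
pair fits `rate ~ predictor_baseline + age + sex + education + log10 NfL +
response_baseline` by OLS on complete cases (≥ 10 subjects required; the
response's own baseline absorbs regression-to-the-mean). One
Benjamini–Hochberg family covers all 48 tests (4 WMH predictors × 6
subcortical volumes × 2 directions); significance is FDR < 0.05. Note that
FDR control bounds the expected fraction of false discoveries, not the
probability of any reverse-direction hit — with strong forward couplings the
step-up threshold rises, and occasional single reverse false positives are
the expected behaviour, observed at a rate well below 0.05 per reverse test.

## Orchestration and reproducibility

`run_full_analysis` executes simulate → validate → group-compare → DEBM →
cross-lag, writing plain CSV/JSON artifacts and a manifest (package
version, SHA-256 config hash, per-stage seeds, exclusion counts, bootstrap
and CV settings). Every stochastic operation takes an explicit seed; reruns
with the same config are byte-identical. Input tables are checked for
required columns, ICV-normalised volumes inside (0, 1), positive WMH
volumes, non-carrier/control consistency, and per-subject baseline visits;
schema failures exit with code 2 and convergence failures with code 3.

## Problem sizes of the validation battery

Ordering recovery uses 20 seeds of the 480-subject cohort; optimiser oracle
checks 100 random 6-biomarker instances against the exhaustive
720-permutation minimum; mixture recovery uses 10 seeds at n = 1000;
directionality uses 50 seeds at the 83-subject longitudinal size; type-I
calibration uses 1000 simulations per test family. The full battery runs in
roughly three minutes on one CPU.

## Known limitations

- The generator's event rule is deterministic given the latent stage; real
  cascades have subject-level ordering heterogeneity.
- Equal-spaced event thresholds tie event timing to ordinal position;
  unequal spacing would change stage distributions but not the ordering
  machinery.
- The per-label mixing fractions assume the three diagnosis labels are
  exchangeable strata within a biomarker; site or scanner strata are not
  modelled.
- Cliff's delta is used as the pairwise effect size; other dominance
  measures would order groups identically but scale differently.
- The cross-lag models are per-pair OLS, not joint mixed-effects
  trajectories; with more visits per subject a mixed model would use the
  within-subject covariance more efficiently.
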