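# Methods

## Scope and model

`metabosig` implements the statistical core of a two-arm pharmaco-metabolomics
analysis: a cohort of ALS patients randomised to an investigational compound
(arm O) plus riluzole, or placebo (arm P) plus riluzole, profiled on a
targeted 188-metabolite plasma panel at one month (V1) and twelve months
(V12), with clinical progression tracked by ALSFRS-r, slow vital capacity
(SVC), manual muscle testing (MMT) and BMI. Three questions are asked of such
data:

1. does the treatment leave a metabolic fingerprint (arm discrimination at
   V1, V12, and in the V1→V12 percent change);
2. which metabolite changes track clinical decline (per-arm association of
   the percent-change metabolome with each clinical percent change);
3. does the *early* (V1) metabolome predict subsequent decline (dichotomised
   progression classes, minimal-signature selection, independent bootstrap
   validation).

## Panel

The shipped panel (`data/panel_p180.csv`) emulates an AbsoluteIDQ-p180-style
kit: 188 named metabolites, 146 measured by flow-injection analysis
(40 acylcarnitines, 14 lysoPC, 38 diacyl-PC, 38 acyl-alkyl-PC, 11 SM, 5
SM-OH) and 42 by LC (21 amino acids, 20 biogenic amines, 1 hexose). The
binding constraints are the totals 188 / 146 FIA / 42 LC and the class→method
mapping; the within-block counts are an emulation, not a transcription of any
vendor list. Three enzyme-activity proxy ratios are defined on top of the
panel (Cit/Arg, Kynurenine/Trp, Putrescine/Orn) and enter every model as
additional features, computed on linear concentrations before the log
transform (log(ratio) = difference of logs keeps the feature space
consistent).

## Synthetic cohort generator

The generator is first-class, tested code: it produces cohorts with the
statistical structure the analysis assumes, plus the ground truth needed to
test every downstream stage.

* **Concentrations.** Log-normal around deterministic class-typical plasma
  medians (amino acids ~tens of µM, acylcarnitines and amines ~0.1–10 µM,
  PC/SM single- to double-digit µM, hexose ~5 mM; medians drawn once from a
  fixed generator and frozen as part of the panel definition). The log-scale
  SD (`noise_sd`, default 0.35) splits 70/30 into a between-subject and a
  within-subject (visit) component.
* **Treatment effect.** Arm O is shifted on designated metabolites
  (default Gly −0.8, Kynurenine +0.8, Cit −0.5, Arg +0.5, in units of
  `noise_sd`) at both visits — the drug is on board from before V1.
* **Progression.** A standard-normal latent rate `z` per subject drives
  (a) the clinical percent declines — each variable gets
  mean + sd·(0.8·z + 0.6·ε) with trial-typical one-year decline magnitudes
  (ALSFRS-r 21 ± 15 %, SVC 20 ± 25 %, MMT 21 ± 18 %, BMI 2.2 ± 6.7 %) — and
  (b) the sphingomyelin progression markers (default SM C24:1 and
  SM OH C22:2 at coupling 0.7, SM C16:1 at 0.5), which receive the coupled
  shift both in the subject baseline (fast progressors differ already at V1,
  which is what makes early prediction possible at all) and again at V12
  (the marker tracks progression, which is what the percent-change
  association sees).
* **Censoring and missingness.** Values below a per-metabolite detection
  floor (the `missing_rate` quantile of the generative distribution) are
  reported as 0; optional death-censoring removes the V12 visit of the
  fastest-declining SVC decile.
* **Clinical baselines** (V1) use the per-arm means/SDs of the emulated
  trial population (e.g. ALSFRS-r 39.5 ± 5.2 in arm O, 38.5 ± 6.1 in arm P);
  ALSFRS-r is integer-valued and clipped to 0–48.

What the generator does **not** emulate: analytical batch effects, plate
drift, QC replicates, heavy-tailed or correlated-block lipid co-regulation,
informative dropout. Passing tests therefore demonstrate correctness of the
statistical machinery under a clean generative model, not performance on
real plasma data.

## Preprocessing

Zeros/missing are imputed as half the minimum positive value of the
metabolite column; ratios are appended on linear concentrations; visit-level
views are natural-log transformed (the base is a convention; no downstream
conclusion is rank-sensitive to it); the percent-change view is
100·(V12−V1)/V1 on linear values. Columns are autoscaled (unit variance) by
default. Clinical progression responses use the percent-*loss* convention
(positive = worsening); classification tasks dichotomise at the median
within the analysed group (configurable: tertile split or fixed threshold).
The median split is an assumption — the source workflow fits
class-discriminant models against clinical variation without stating its
dichotomisation.

## PLS / OPLS-DA core

NIPALS with a single response column; binary classes coded {0, 1}, centred,
predicted at the 0.5 threshold; 200-iteration cap per component with
convergence recorded. OPLS-DA removes class-orthogonal components
(w_o ∝ p − (wᵀp/wᵀw)·w) before a single predictive component; predictive and
orthogonal scores are exactly orthogonal by construction. Diagnostics:

* **VIP** with the standard normalisation (mean VIP² = 1);
* **p(corr)**: correlation of each scaled feature with the first predictive
  score;
* **Q2(cum)** from stratified 7-fold cross-validation (each sample predicted
  once). Default is the additive rule Q2 = 1 − PRESS/SS where SS is the
  cross-validated sum of squares of the mean-only model, so a model that
  predicts the training mean scores exactly 0; a per-component
  multiplicative rule is available (`q2_rule`);
* **CV-ANOVA**: F = [(SS0 − PRESS)/(DF0 − DF)]/[PRESS/DF] with DF0 = N−1 and
  model DOF = number of fitted components (predictive + orthogonal) — a
  literature-standard approximation of the commercial bookkeeping;
* **jack-knife** weight SEs from the CV sub-models after sign alignment
  (alignment correlation < 0.3 flags the interval unstable);
* **status rules**: rejected if Q2 < 0, or Q2 < 0.05 with any component
  "eigenvalue" (tᵀt/(N−1), which is how we read the undefined term) above 2;
  robust if Q2 > 0.40 and R2Y > 0.50; acceptable otherwise.

Model complexity is chosen by adding components (orthogonal for OPLS-DA,
predictive for PLS) while Q2 improves by > 0.01, capped at 3; an OPLS-DA that
never benefits from an orthogonal component falls back to 1-component
PLS-DA. Variable exclusion then removes the lowest-VIP feature (ties: lower
|p(corr)|, then name) one at a time, keeping the best-Q2 model, stopping
after 5 removals without improvement or at 3 features; complexity is fixed
once on the full table rather than re-scanned per removal.

## Tiered signature selection

Per classifier (PLS-DA with VIP ranking, random forest with
impurity-decrease importance, linear SVM with |weight|), rounds of:

1. 50 stratified bootstrap train/test splits (training set drawn with
   replacement preserving class proportions, test = out-of-bag subsampled to
   `test_fraction` = 0.2);
2. importance ranking aggregated by mean rank across bootstraps;
3. a half-interval (binary) search over prefixes of the ranking. A prefix
   passes when, after within-column permutation of all *other* features in
   the test sets, the out-of-bag majority-vote accuracy per sample is
   (a) significantly above the majority-class rate and (b) not significantly
   below the intact-model accuracy (one-sided binomial tests);
4. restriction to the selected prefix and repetition until two consecutive
   rounds select the same set, or 10 rounds.

Tier S = selected in every round, A = in every round but the last, E = in an
earlier round only.

Two statistical choices matter here. Accuracy is aggregated per *sample*
(majority vote over the bootstrap test sets the sample appears in) because
pooled predictions across overlapping out-of-bag sets are strongly
correlated and a pooled binomial test is anti-conservative. And the
above-chance test is Bonferroni-corrected by the number of candidate
features the selection started from: the tested prefix is the top of an
importance ranking over p features, so its null distribution is a maximum
over p spuriously correlated columns; without the correction a best-of-p
noise feature is selected in a large fraction of null datasets. The
correction carries the original p through later rounds, since restricting
the feature set does not refresh the data the maximum was selected on. The
drop test (b) is kept at the uncorrected level — its leniency direction is
reversed. The standalone `relevance_test` operation keeps the plain
single-test semantics (degenerate at alpha = 1, where everything passes).

With 74–80 samples the effect sizes at which a true marker is separable from
the best of ~190 null features overlap; the selector is therefore tuned to
keep the tier-S false-selection rate low at the cost of sometimes parking
genuine markers in tier A (round-1 selection not reconfirmed), which is why
downstream consumers use S∪A as the signature.

## Independent validation

For a fixed feature set, 1000 stratified random train/test splits
(test = 1/3) with a 100-tree random forest per split; sensitivity,
specificity, PPV and NPV from each test-set confusion matrix, reported as
per-metric medians over the splits where the metric is defined (splits with
an empty denominator are excluded and counted, never coerced to 0). The
validation uses simple random splits rather than out-of-bag bootstrap —
it is meant as an independent check, not a repeat of the selector's
resampling.

## Problem sizes in tests and the acceptance script

The test-suite and acceptance-script runs use the default cohort
(38 + 36 subjects, 188 metabolites + 3 ratios) throughout; resampling depths
are the package's scaled defaults for routine runs — 200–1000 validation
splits (medians stabilise well below 200 at these sample sizes; the
200-vs-1000 difference is ~2–3 percentage points), 25–50 bootstraps per
selector round, 50-tree ranking forests / 100-tree validation forests.
The full-study driver (`run_full_study`) executes 3 discrimination, 8
association and 12 prediction models in one pass and records individual
model failures in the bundle instead of aborting.

## Known limitations

* The selector's binomial tests treat majority-vote accuracies as binomial
  counts; residual correlation between samples' votes makes the tests
  slightly anti-conservative, which is visible as occasional single-feature
  tier-S selections on pure-noise data (~5–10 % of datasets at default
  settings).
* Q2 conventions, CV-ANOVA degrees of freedom and the "eigenvalue" reading
  approximate, but do not bit-reproduce, the commercial chemometrics
  software the workflow emulates.
* The generator's clean log-normal world makes recovery rates upper bounds
  on what identical settings would achieve on real plasma data.
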