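# Methods

## Problem setting

Patients with septic shock are randomized to control, hydrocortisone, or
hydrocortisone + fludrocortisone; the outcome is death by day 90 (secondary:
day 28).  The package estimates (i) the average treatment effect (ATE) of
each regimen contrast, (ii) two per-patient individual treatment effects
(ITEs), and (iii) the net benefit of treatment policies built on those ITEs,
on pooled multi-trial cohorts.  Because the underlying patient-level trial
data are not public, all empirical claims are made on synthetic cohorts with
known counterfactual structure.

## Synthetic cohort generator

One row per patient: trial label, baseline covariates (age, sex, admission
category, SAPS II, SOFA, infection origin/site, pathogen class, baseline
cortisol, cortisol increment after 250 µg corticotrophin, lactate, glucose,
maximal norepinephrine-equivalent dose, mechanical ventilation), assigned
arm, 28/90-day outcomes, and — unique to simulation — per-arm true risks and
potential outcomes.

**Marginals.** Continuous covariates use a truncated normal (age, SAPS II,
SOFA) or shifted log-normal (right-skewed laboratory values) whose
parameters are solved so the distribution's quartiles equal the published
median/IQR of the pooled cohort: age 66 (55–76) years, SAPS II 55 (42–69),
SOFA 11 (9–13); 65% men.  Quantities not published at that granularity
(cortisol 20 [12–34] µg/dL, increment 7 [3–15] µg/dL, lactate 3.0 [1.8–5.5]
mmol/L, glucose 8.0 [6.2–11.5] mmol/L, norepinephrine 0.5 [0.2–1.0]
µg/kg/min, 80% ventilated, 40% hospital-acquired, site/pathogen mixes) are
field-realistic defaults for vasopressor-dependent septic shock chosen once
and fixed.  Covariates are drawn independently; inter-covariate correlation
is not reproduced (nothing to calibrate it to), which mainly matters for how
optimistic model discrimination looks (see Limitations).

**Trial structure.** Four trials with enrollment weights 299/499/509/1241
and their historical arm structures: trial 1 control vs combination, trial 2
control vs hydrocortisone, trial 3 hydrocortisone vs combination (no
placebo), trial 4 control vs combination, all 1:1.  Trial-specific
intercepts (+0.30, −0.20, −0.10, 0 log-odds) encode between-trial mortality
differences.

**Outcome model.** Control-arm 90-day risk is logistic in severity and
infection covariates.  Each active regimen shifts the log-odds by

    effect(arm, W) = main + b_saps·(SAPS2 − 55) + b_resp·(responder − 0.41)

with `responder = 1{cortisol increment ≥ 9 µg/dL}`, `b_saps < 0`,
`b_resp > 0`: sicker corticotrophin-nonresponders benefit most, and mildly
ill responders are harmed (a qualitative interaction, so the two ITE
estimators genuinely disagree in sign structure).  Main effects (−0.24
hydrocortisone, −0.16 combination) put the implied pooled relative risks
near 0.88/0.92 at ~49% control mortality.  The global intercept is solved
(once, 200k-draw fixed-seed Monte Carlo + Brent root finding) so the
marginal assigned-arm mortality is 47.7%.  Potential outcomes share one
uniform draw across arms (comonotone coupling); `y28 = y90 AND
Bernoulli(0.75)` enforces endpoint nesting.

**Missingness.** Per-covariate mechanisms: missing completely at random for
baseline cortisol/lactate/glucose, and value-dependent (missing *not* at
random, `P(miss) = expit(a + b(x − c))` with `b > 0`) for the cortisol
increment — high increments are blanked more often, biasing the observed
mean downward by construction.  Binary `miss_*` indicators accompany every
covariate; outcomes, arm, and severity scores are never blanked.

**Seeds.** A single master seed spawns substreams (covariates,
randomization, outcomes, missingness) via `numpy.random.SeedSequence`;
identical arguments give byte-identical cohorts.

## Estimators

**TMLE.** For a two-group contrast with outcome `Y`, treated indicator `A`,
initial predictions `Q(a, W)` (clipped to [10⁻³, 1−10⁻³]) and treated
probability `g` (truncated to [0.01, 0.99]; known or per-trial empirical in
randomized cohorts, logistic-in-covariates for observational use), a single
logistic fluctuation with covariate `H = A/g − (1−A)/(1−g)` and offset
`logit Q` is fitted by IRLS.  The fluctuation MLE solves the efficient-score
equation, so the ATE influence curve has mean zero (asserted to 10⁻⁸);
variances come from the sample variance of the influence curve, the RR
interval from the delta method on the log scale, p-values from two-sided
Wald tests.  With no covariate adjustment and constant known g the procedure
collapses analytically to the difference in sample proportions.  Trials
lacking one of the contrast groups (e.g. the no-placebo trial in any
any-steroid-vs-control analysis) violate positivity and are excluded with a
warning; pooled analyses include trial as a covariate in the initial fit
(per-trial stratified estimates are also produced).

**Super Learner.** Ten base-learner families (plain and interaction
logistic regression, L1-path logistic selected by CV as a stepwise-selection
analogue, ridge-MAP logistic as a Bayesian GLM analogue, spline-basis
logistic additive model, additive stump boosting in the spirit of adaptive
regression splines, gradient boosting, random forest, calibrated linear SVM,
RBF SVM).  Level-1 honest predictions come from stratified 10-fold
refitting; the metalearner maximizes the cross-validated AUC of the convex
combination.  AUC is piecewise constant in the weights, so the search is
direct: exact evaluation at the simplex vertices and the uniform mixture, a
deterministic coarse simplex grid for libraries of ≤5 learners, and
multistart Nelder–Mead on softmax-parameterized weights; the first candidate
(in a fixed order) attaining the maximum wins, so ties break
deterministically.  Duplicate level-1 columns are merged (weight to the
first occurrence) and constant columns dropped before the search — neither
can change any ranking — which makes the degenerate-library identities exact.
Discrete selection (`meta="discrete"`) is available.  Because the vertices
are always candidates, the ensemble's CV-AUC never falls below the best
single learner's.  Failed learners are dropped with a warning; an empty
surviving library is a hard error.

Features: standardized continuous covariates (median-imputed), one-hot
categoricals (mode-imputed), the missingness indicators, trial dummies, a
3-level treatment factor, and treatment × SAPS II / treatment × cortisol
increment interaction columns so parametric learners can express effect
heterogeneity.  Counterfactual prediction overrides the treatment feature at
transform time.

**ITEs.** `ite_saps2(p0, RR) = p0·(1 − RR)` with `p0` always from the SAPS
II equation (never the ensemble) and per-regimen empirical RRs 0.88/0.92 by
default (configurable); by construction every patient's effect shares the
sign of `1 − RR`.  `ite_optimal` is the counterfactual risk difference
`P̂(Y|control, W) − P̂(Y|a, W)` per active regimen from the Super Learner;
the scalar `D` is the maximum over regimens and the recommended regimen the
argmax, ties resolved toward hydrocortisone alone (the simpler regimen).
No per-patient confidence intervals are produced.

**Net benefit.** `Threshold` pairs `T ∈ (0,1]` with `NWT = 1/T` exactly.
Treat-all: `ATE − T`.  Threshold rule "treat if `D_i > T`": the event-rate
decrease is the population average `E[D·1{D>T}]` — treated patients
contribute their effect, untreated contribute zero — minus
`P[D>T]·T`.  This reading (rather than the mean of `D` among the treated) is
the one consistent with the decrease-in-event-rate definition and collapses
correctly to treat-none (`D ≤ T` everywhere) and treat-all (`D > T`
everywhere).  The oracle variant scores an arbitrary assignment rule against
the actual potential outcomes of a synthetic cohort.  Curves default to the
integer NWT grid 2–100 with B = 500 percentile-bootstrap bands; resampling
is stratified by trial and indexes per-stratum *sorted* effect values, so
bands depend only on the multiset of patient values (order-invariant) and
the seed.

**Evaluation.** AUC by Mann–Whitney with half-credit ties; variance by
DeLong placement components; pooled (not fold-averaged) out-of-fold CV-AUC
with one DeLong interval on the pooled vector; Brier score; equal-frequency
decile calibration bins with Wilson intervals plus a lowess smooth for
plotting.

**Decision tree.** sklearn CART (Gini, minimum leaf 20) on the binary label
`1{D_i > T}`; the cost-complexity parameter is chosen over the pruning path
by 20-fold cross-validation with the one-standard-error rule (largest
penalty within 1 SE of the minimum CV error).  Regression on `D` itself is
available.  Single-class labels return a root-only tree with a warning.

## Numerical choices and problem sizes

Probabilities are clipped to [10⁻³, 1−10⁻³] before any logit; propensities
truncated to [0.01, 0.99]; fluctuation fitted to IRLS tolerance 10⁻¹².
Generator calibration targets are solved to 10⁻¹⁰ (Brent) or 10⁻⁶ (hybrid
Powell for truncated-normal quartiles).  Simulation studies in the test
suite use cohorts of 400–4000 patients, 500 replicates of n = 1000 for the
TMLE recovery/coverage study, and the 4-learner compact library — sizes at
which each study completes in seconds to a couple of minutes while holding
Monte-Carlo error well below the margins being asserted.  Calibration
checks separate the generator's process-level event rate (mean assigned-arm
true risk, binomial-noise-free) from the realized death rate, which is
compared on the across-seed average.

## What the synthetic studies do and do not show

Passing tests demonstrate that the estimators are correct *on data whose
generating process is known*: TMLE is unbiased with nominal coverage, the
ensemble is honest (permuted labels give chance CV-AUC) and never worse than
its best member, the threshold rule is decision-theoretically optimal
against true effects, and the tree recovers planted structure.  They cannot
certify performance on the real trials: the generator draws covariates
independently, uses a single qualitative-interaction effect structure, omits
time-to-event information and real between-trial heterogeneity beyond
intercepts, and its missingness mechanisms are stylized.  Published
real-data figures (pooled RR 0.89, AUCs 0.64/0.74/0.77, Brier 0.21, net
benefit 0.31 at NWT 25) guided the realism of the scenarios but are not
reproducible without the trial data and are not asserted.

## Known limitations

* The any-steroid contrast excludes the trial without a placebo arm
  (positivity); its patients still inform per-regimen contrasts.
* The hydrocortisone-vs-combination contrast is informed by a single trial
  under the default structure.
* The AUC metalearner search is exact only up to its grid/multistart
  resolution for libraries larger than five learners.
* `ITE_SAPS2` inherits the SAPS II equation's known overestimation of
  absolute risk; it is used as specified, not recalibrated.
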