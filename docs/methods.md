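# Methods

## The problem

Milestone-entry cohorts — biobanks, genomic-testing registries, specialty
EHR databases — record a patient only after some event later than the
natural time origin (e.g. a comprehensive genomic test received months
after diagnosis). Survival measured from the origin is then
*left-truncated*: patients who died before the milestone never enter the
data, so the observed sample over-represents long survivors. A model fit
naively on such data inherits this *immortal-time bias*: baseline risk is
underestimated, survival probabilities are overestimated, and coefficients
of predictors associated with entry time are distorted. These data are
also typically high-dimensional (hundreds of mutation indicators), calling
for penalized regression.

`ltrcnet` implements the combination: elastic-net penalized Cox
proportional hazards regression whose risk sets respect delayed entry,
plus the prediction, evaluation and simulation machinery needed to study
the bias end-to-end.

## Model and estimation

The hazard is h_i(t) = h0(t) exp(x_i'β). With data (v_i, y_i, e_i, x_i)
— entry time, observed time, event flag, predictors — the Breslow-tie
partial likelihood is evaluated over entry-adjusted risk sets

    R*_i = {j : y_j ≥ t_i > v_j},

i.e. subject j is at risk only strictly after its entry time (a subject
entering exactly at an event time is excluded; ties among event times
share one denominator). Setting all v = 0 recovers the standard
right-censored model exactly.

The fitted objective is

    max_β  (2/n) · pll(β) − λ [ α‖β‖₁ + ½(1−α)‖β‖₂² ],

solved along a decreasing λ path (default 100 points, log-spaced from
λ_max down to 0.01·λ_max when n > p, 0.05 otherwise) by outer
iteratively-reweighted least squares and inner cyclical coordinate
descent with soft-thresholding. Predictors are standardized internally
(plain sample mean/SD); coefficients are reported on the original scale.
Note the λ in this objective is twice the λ of implementations that scale
the log-likelihood by 1/n (glmnet and its ports); the tests account for
this factor when cross-checking.

Numerical design:

* **Risk-set sums.** A subject is at risk on the interval (v_j, y_j], so
  every risk-set sum is a difference of suffix sums over subjects sorted
  by exit and by entry time: O(n log n) setup, O(n) per reweighting.
  Empty adjusted risk sets (an event before anyone has entered) raise an
  error at structure-building time. The linear predictor is centred
  before exponentiation (the partial likelihood is shift-invariant), and
  clipped at ±250 to prevent overflow.
* **IRLS weights** are the diagonal of the negative Hessian,
  w_j = r_j A_j − r_j² B_j with A, B the cumulative-hazard-type sums over
  the subject's at-risk window; subjects with w_j = 0 (no remaining risk
  set) drop out of the weighted least-squares pass. Working responses are
  z_j = η_j + (e_j − r_j A_j)/w_j.
* **Convergence.** The outer loop stops when the maximum standardized
  coefficient change falls below `tol` (default 1e-5, giving KKT
  residuals well under 1e-4, the accuracy the oracle comparisons
  require). Inner coordinate descent is solved inexactly early on — its
  tolerance tracks one tenth of the current outer step (a standard
  inexact-Newton forcing sequence) and tightens to `tol` as the outer
  loop converges. A step-halving safeguard keeps the penalized objective
  non-decreasing across outer iterations. Non-convergence at a λ is
  flagged in the result, not fatal.
* **Screening.** Sequential strong rules prefilter coordinates at each λ;
  a full KKT check over all predictors catches violations and refits.
  Zero-variance predictors are excluded with a warning.
* **Path truncation.** `fit_path` stops early (glmnet's convention) once
  the explained fraction of null deviance exceeds 0.99 or grows by less
  than 1e-5 of itself per step. Ridge (α = 0) has no finite λ_max; the
  path is anchored with the α = 0.001 surrogate.
* The inner coordinate-descent kernel is compiled with numba; everything
  else is numpy.

## Cross-validation

K-fold (default 10) cross-validation scores each λ with the
Verweij–Van Houwelingen partial-likelihood deviance
D_k = −2[pll_full(β̂₋ₖ) − pll₋ₖ(β̂₋ₖ)], which remains well-defined even
though Cox partial likelihoods do not decompose over folds; λ_min
minimizes the across-fold mean and λ_1se is the largest λ within one
standard error of it. The full-data path and all fold paths are advanced
down the λ grid in lockstep (all warm-started), and the descent stops
once the mean CV deviance has not improved for 10 consecutive λ values
(`stop_patience`; `None` scores the whole grid). For the convex-shaped
CV curves of lasso paths this skips only the saturated overfit tail,
which the minimum-deviance rule never selects but which dominates compute
in high dimensions.

## Prediction and evaluation

* **Breslow baseline hazard**: cumulative-hazard increments
  d_i / Σ_{j∈R*_i} exp(x_j'β̂) at each event time; survival curves are
  S(t|x) = exp(−H0(t) exp(x'β̂)) with right-continuous step
  interpolation.
* **Kaplan–Meier with delayed entry**: at-risk counts
  n(t_i) = #{j : v_j < t_i ≤ y_j}. With all entries zero this is exactly
  the textbook estimator.
* **Harrell's C-index** from risk scores (the linear predictor; higher =
  worse): comparable pairs are those where the shorter observed time ends
  in an event; score ties count ½. Entry times play no role in pair
  formation — the C-index is computed on whichever subjects are scored
  (observed vs complete sample), which is where the truncation story
  enters. Implemented via lifelines' concordance routine; an exhaustive
  pair-enumeration oracle backs it in the tests.
* **Calibration curves**: at each evaluation time (default 0.5, 1, 2
  years) subjects are ranked by predicted survival, cut into equal-count
  deciles (stable sort; bin 1 = lowest predicted survival), and each
  decile's mean predicted probability is compared with the KM estimate
  inside the decile — entry-adjusted KM when the evaluated subjects are
  themselves left-truncated (observed samples), plain KM on complete
  simulated samples where everyone is followed from time zero. Bins
  under 10 subjects, or whose KM curve ends before the evaluation time
  (value carried forward), are flagged.

## The synthetic cohort generator

The generator emulates the structure of an oncology clinico-genomic
cohort (times in years):

* **Binary alterations**: p̃ correlated binaries from a latent
  multivariate probit. The correlation matrix is a scaled Wishart-type
  draw (G'G with G standard normal, rescaled to unit diagonal — clipped
  to PSD if numerically indefinite); marginal prevalences π_k ~
  U(0.2, 0.8) enter through thresholds Φ⁻¹(π_k). With many variables the
  pairwise correlations concentrate near zero (scale ~ p̃^{-1/2}).
* **Effects**: each binary coefficient is nonzero with probability 0.5,
  then U(−0.25, 0.25) — hazard ratios between 0.78 and 1.28.
* **Clinical stand-ins**: 11 additional covariates (6 standard-normal
  continuous, 5 Bernoulli with prevalences 0.3–0.7) represent the
  registry variables of the real cohort, which are license-restricted
  and cannot be shipped; their coefficients were drawn once from
  U(−0.3, 0.3) and are frozen constants. This preserves the dimensions
  of the two study scenarios (p = 21 and p = 1011) and the mixed-type
  structure, not the real variables' joint distribution.
* **Survival**: proportional-hazards Weibull,
  f(t) = a m t^{a−1} e^{−m tᵃ}, with log m_i = α + x_i'β − mean(x'β);
  the centring makes population-average survival match the
  intercept-only model. Defaults a = 1, α = log log 2 (median latent
  survival exactly 1 year, exponential hazard) — chosen as a realistic
  stand-in for the advanced-cancer setting since the real calibration
  targets are not published. Censoring is an independent Weibull with
  median 2 years (event fraction ≈ 2/3 before truncation).
* **Entry**: two-part model — probability 0.2 of entry exactly at time
  zero, otherwise lognormal. The lognormal parameters are derived from
  two stated moments: median 1 ⇒ μ = 0; mean 1.6 ⇒ σ² = 2 ln 1.6
  (verified analytically: exp(μ + σ²/2) = 1.6). The source description
  of the mixing weight is internally contradictory (its prose and its
  printed equations assign π̃ to opposite branches); this package uses
  the 20%-at-zero reading, which reproduces the published entry-time
  tail among observed subjects, the discrimination table and the
  calibration-bias figures, whereas the opposite reading yields ~13%
  truncation and nearly bias-free samples in which none of those
  published phenomena appear.
* At these defaults roughly half the cohort is truncated (V > Y), and
  about 12% of *observed* subjects entered more than a year after
  diagnosis.

What the generator does **not** emulate: dependence between entry time
and survival (dependent truncation), real mutation co-occurrence
patterns, non-proportional hazards, covariate-dependent censoring, and
the real cohort's variable panel drift/missingness. Passing tests
therefore demonstrate correctness of the estimators and the *mechanism*
of immortal-time bias, not performance on any particular real dataset.

## The replicate protocol

One replicate: generate a cohort (default n = 5000), split 75/25,
keep the observed (non-truncated) training subjects, fit lasso Cox
models with and without the left-truncation adjustment (λ by 10-fold CV
deviance minimization), then evaluate on the test set twice — on its
observed subset and on the complete sample (truncated + non-truncated, a
quantity only a simulation can provide). Outputs per replicate: the four
C-index cells (adjustment × test sample) and decile calibration tables.

The intercept-only Weibull MLE utility maximizes the
truncation-conditional likelihood Σ e log f(y) + (1−e) log S(y) − log
S(v) (BFGS on (log a, log m) with analytic gradients); fitting with the
censoring indicator reversed estimates the censoring distribution, the
same device the calibration procedure uses.

## Problem sizes used in the shipped checks

The acceptance script averages 20 replicates of the high-dimensional
scenario (n = 5000, p = 1011) — Monte-Carlo SE of each reported mean
C-index ≈ 0.003 — and uses 10⁶ draws for the entry-time moments. The
calibration-direction check uses one small-p replicate with a complete
test sample of 5000 subjects (cohort n = 20 000), where per-decile KM
noise (SE ≈ 0.02) is small against the bias being demonstrated. Brute-
force equivalence checks enumerate risk sets explicitly on 1000 random
datasets with n ≤ 8.

## Known limitations

* Breslow tie-handling only (no Efron); no time-varying covariates,
  stratification, observation weights, interval censoring or recurrent
  events.
* The C-index is the standard Harrell estimator; no truncation-aware
  pair rule is attempted.
* λ_max for pure ridge is anchored by a surrogate mixing value, not an
  exact bound.
* CV's `stop_patience` assumes an approximately convex CV-deviance
  curve; a pathological multi-dip curve could in principle stop before a
  deeper later minimum (disable with `stop_patience=None`).
* Probability rescaling of survival predictions (Platt/isotonic) is out
  of scope.
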