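# Methods

## The problem

In randomized trials of perceptible treatments — psychedelics being the
sharpest case — participants often infer their assignment from the
treatment's acute effects ("functional unmasking").  Post-treatment
*expectancy* E (hope about how one's outcome will change) can then differ
between arms and partially mediate the measured effect.  Randomization
still identifies the average treatment effect (ATE): unmasking is a
*mediation* phenomenon, not confounding, because belief B and expectancy E
sit downstream of the randomized treatment A.  But the ATE may not be the
estimand of interest, and the intuitive fixes — stratifying on belief,
reweighting arms to balanced expectancy — condition on post-treatment
colliders and can be biased strongly enough to reverse the sign of a
beneficial effect.

The package implements the estimand-first alternative: the **controlled
direct effect**

CDE(e) = E[Y(a=1, e) − Y(a=0, e)],

the between-arm contrast in a world where expectancy is set to a common
level e in both arms, and the **treatment-fixed CDE of expectancy**

tfCDE(a; e1, e0) = E[Y(a, e1) − Y(a, e0)],

the within-arm effect of expectancy itself.  Identification requires that
E be as good as randomized given baseline covariates X, treatment A and
post-treatment confounders Z of the E→Y path (e.g. trip intensity, early
outcome readings).  Whether an analysis isolates pre- or post-efficacy
expectancy effects is carried entirely by the Z schema: post-efficacy
analyses must declare early outcome measurements as members of Z; the
estimators themselves are agnostic.

## Estimators

Write p_a(x) = P(A=a|X), π_e(x,a,z) = P(E=e|X,A,Z),
μ(x,a,z,e) = E[Y|X,A=a,Z,E=e], and η(x,a) = E[μ(X,a,Z,e)|X=x,A=a]
(the sequential-regression projection).  For ψ(a,e) = E[Y(a,e)]:

* **g-computation**: ψ̂ = n⁻¹ Σᵢ η̂(Xᵢ, a).
* **IPW**: ψ̂ = n⁻¹ Σᵢ 1{Aᵢ=a, Eᵢ=e} Yᵢ / (p̂_a π̂_e), optionally
  Hájek-normalized within the (a,e) cell (the default; the
  Horvitz–Thompson variant is kept because it is the one that coincides
  with g-computation on saturated data).
* **doubly robust**: the sequential-regression influence-function
  estimator, averaging

  1{A=a, E=e}/(p_a π_e) · (Y − μ) + 1{A=a}/p_a · (μ − η) + η,

  consistent if either (μ, η) or π_e is correct, with standard errors from
  the empirical variance of the per-subject contribution contrasts.

On fully discrete data with saturated nuisances fit in-sample and
empirical treatment propensities, the three estimators are algebraically
identical; the test suite asserts agreement to 1e-10 and equality with a
brute-force double summation of the g-formula.

The critiqued baselines are implemented faithfully and labelled
`BIASED_DEMO`: within-belief arm contrasts, and the expectancy-rebalancing
weights w = p_pooled(E)/p_arm(E).  The rebalanced contrast targets
Σ_e p_pool(e)·(E[Y|A=1,E=e] − E[Y|A=0,E=e]), which under the collider
generating process equals β_A + β_U·Σ_e p_pool(e)·(E[Z|1,e] − E[Z|0,e]) —
same collider structure as stratification, hence the same sign reversal.

For sequentially randomized designs, regime means are estimated by
stabilized-inverse-probability-weighted means of the final outcome among
exact regime matches (marginal structural model with a saturated regime
mean model).  Under marginal randomization the stabilized weights are
identically 1; with response-conditional randomization, per-timepoint
logistic models produce numerator (assignment history only) and
denominator (full history) probabilities.  Weights are truncated at the
99th percentile by default and the truncated fraction, mean weight, and
effective sample size (Σw)²/Σw² are reported.  The stabilized numerator is
marginal (no baseline conditioning) — the simpler convention, chosen
because the package's designs randomize marginally by default.

## Nuisance fitting

Nuisances are cross-fitted (default 5 folds; 2 in most demonstrations for
speed): a subject's predictions come only from models trained without its
fold.  `n_folds=1` fits in-sample and exists for the saturated-equality
regime, where the algebraic identity requires in-sample empirical
frequencies; this deliberately relaxes the usual ≥2-fold rule for that
special case.  Learner families: regularized linear/logistic (default
below n=1000), histogram gradient boosting (above), k-NN, and saturated
cell-mean/cell-frequency models for discrete problems.  Probability
outputs are clipped to [δ, 1−δ] with δ=0.01 by default; pre-clipping
ranges and clipped fractions are always surfaced in diagnostics, and δ=0
is allowed where exactness matters.  In randomized designs the treatment
propensity can be fixed at its known value.  The outcome regression is fit
within the (A=a, E=e) cell on (X, Z) features — the estimators never fix
expectancy by subsetting *alone*; subsetting only ever feeds the g-formula
averaging over Z|X,A.

Standard errors: influence-function SEs for the DR estimator; a
nonparametric bootstrap that refits the nuisances on every resample for
g-computation and IPW (500 replicates by default, fewer in the examples
and tests where runtime matters more than third-digit SEs).

## Synthetic worlds and what their oracles certify

Each generator emits an `OracleTruth` computed by intervening on its own
generating equations — closed form, numeric integration, or counterfactual
Monte Carlo with common random numbers — never by running an estimator.
Common random numbers make null configurations produce *exactly* equal
regime means and shrink the Monte-Carlo error of contrasts.  One
deterministic stream per randomness block means enlarging n appends
subjects without reshuffling earlier ones.

**Collider world** (belief stratification).  Z ~ N(0,1) is a responder
trait; A ~ Bern(½); B = 1{κ₀ + κ_A·A + κ_U·Z + logistic noise > 0};
Y = y₀ + β_A·A + β_U·Z + σ_Y·ε, a change-from-baseline severity score on a
CAPS-like scale (beneficial = negative).  Expectancy is operationalized as
belief.  Defaults κ₀=−2.5, κ_A=5, κ_U=3, β_A=−10, β_U=−16, σ_Y=5 were
chosen so that the sign reversal is certified analytically: the oracle
integrates E[Z|A,B] over the trait density and reports the within-belief
stratified truth β_A + β_U·(E[Z|1,b] − E[Z|0,b]) = +2.40 against a true
CDE of −10.  The reversal needs strong belief selection; with a
standard-normal trait the conditional-mean gap between arms is bounded by
φ(0)/½ ≈ 0.8 when the belief threshold is zero, which is why the
configuration uses a negative intercept and a large treatment effect on
belief.  Logistic (not probit) belief noise makes P(B=1|A,Z) an exact
logistic regression, so the "correct propensity" arm of the
double-robustness checks is exactly specifiable.  Robustness tests use a
moderate-overlap variant (κ₀=0, κ_A=κ_U=1) so that propensity clipping
does not entangle with the property under test.

**Vaccine world** (efficacy-expectancy feedback).  Weekly mechanism per
subject: exposure ~ Bern(0.30 × risk level), infection per exposure
0.25 × (1 − 0.5·A), weekly testing, instant non-immunizing cure; with
feedback on, each infection multiplies the risk level (the behavioral
expectancy proxy) by ρ=0.5.  n=10,000 per arm, T=12 weeks.  The
per-exposure risk ratio 1 − VE = 0.5 is closed form and untouched by
feedback; arm-wise expected cumulative-infection trajectories come from
paired counterfactual Monte Carlo.  Feedback shrinks the final-week
between-arm gap because protected (vaccinated) subjects are scared off
less often and drift toward riskier behavior than controls.

**Dose-response world.**  Doses {0,1,2,3} uniformly assigned; binary
expectancy with linear-probability profile P(E=1|d) = 0.2 + α_d·d
(α_d = 0.2); Y = γ_d·d + γ_E·E + β_X·X + noise with γ_E=5, σ_Y=3.  All
truths are closed form: CDE(d vs 0) = γ_d·d, naive per-level trend
γ_d + γ_E·α_d, tfCDE = γ_E.  Full mediation is the γ_d=0 special case.
Binary expectancy (rather than a continuous score) keeps the dose world
inside the estimators' declared-level contract; the closed-form identity
naive = direct + expectancy-slope term is the same either way.

**Sequential world.**  Two timepoints; (A_t, M_t) randomized marginally at
½ each; binary expectancy with logit e₀ + 1.0·M_t + 1.0·A_t +
0.5·(Y_{t−1} − y₀); outcome Y_t = y₀ + carryover·τ·A_{t−1} + τ·A_t +
γ_E·E_t + ε with τ=3, γ_E=1.5, carryover 0.6, σ_Y=1, n=2,000.  All 16
regime means are evaluated by counterfactual Monte Carlo (200,000 draws,
common random numbers).  Because the final outcome is linear in (A₂, E₂),
the final-period CDE fixing E₂ is exactly τ and the tfCDE exactly γ_E;
`flatten_two_period` casts the design as a cross-sectional CDE problem
with the entire first-period history plus the final message in Z, which
is precisely the conditioning set under which E₂ is as good as randomized.

Parameter defaults throughout are the study conditions of the
demonstrations: the vaccine's 50% per-exposure efficacy is the one
externally printed number; the remaining magnitudes were fixed once at
values a trialist would call realistic for their scales (CAPS-like change
scores, weekly STI risk, unit-variance wellbeing scores) and so that every
demonstrated contrast is estimable at the stated n.

## What the generators do not emulate

No dropout, non-adherence or missing data (validation rejects missing
values rather than imputing); no measurement error in E or Z; no contact
network in the vaccine world (independent weekly exposures); expectancy is
binary by default although the schema admits ordinal codings; side-effect
driven (pre-efficacy window) unmasking dynamics are representable through
the schema but not separately simulated.  Passing tests therefore certify
the estimators' statistical behavior under correct identification
conditions, not robustness to violations of them.

## Numerical choices and degenerate inputs

Numeric integration over the trait uses adaptive quadrature on [−12, 12]
(beyond ±12 the normal density underflows the quantities involved).
Regime matching is exact-sequence only; dynamic regimes are out of scope.
Ties/degenerate cases: constant outcomes warn and yield constant
regressions; a single expectancy class inside a training fold raises an
error naming the fold; an empty (a,e) cell raises a positivity error for
IPW/DR and is flagged (not raised) by the positivity report; equal tfCDE
levels short-circuit to an exact zero.  Saturated learners fall back to
the training-set mean for cells unseen at prediction time.

## Problem sizes

The demonstrations run at their design sizes — collider 50,000; vaccine
2 × 10,000 × 12 weeks; dose 20,000; sequential 2,000 with 200,000-draw
oracles — with linear learners and 2 folds where a flexible learner adds
nothing on a linear generating process.  The full test suite and the
acceptance script each complete in well under a minute on one CPU.
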