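# Methods

## The model

`strategylca` analyzes subjects-by-items matrices of binary success
indicators with latent class models (finite Bernoulli mixtures).  Subject
*i* with age *x_i* (months) belongs to one of *K* latent classes
("strategies"); conditional on class *c*, item responses are independent
Bernoulli draws:

    Pr(y_i | x_i) = Σ_c π_c(x_i) Π_j p_cj(x_i)^y_ij (1 − p_cj(x_i))^(1−y_ij)

Age can enter the model in one of three ways (`covariate_mode`):

* `none` — π and p constant; the plain latent class model.
* `membership` — concomitant-variable latent class regression:
  π_c(x) = softmax(α_c + β_c·x) with class 1 as the reference
  (α_1 = β_1 = 0).  One intercept and one slope per non-reference class.
* `response` — per class-item logistic regression:
  logit p_cj(x) = a_cj + b_cj·x.  This is the "same strategy, executed
  more accurately with age" alternative; with K = 1 the per-class /
  per-item distinction vanishes.

The links (multinomial logit for membership, logistic for responses) are
the standard concomitant-variable forms for this model family.  The choice
of one slope per class-item in `response` mode is the more general of the
two possible conventions; the analysis pipeline only uses that mode at
K = 1, where they coincide.

## Fitting

Maximum likelihood by EM with random restarts:

* **Initialization** — response probabilities ~ U(0.2, 0.8), class weights
  ~ symmetric Dirichlet(1), covariate slopes 0.  Default 20 restarts; one
  master seed spawns one sub-seed per restart, so fits are reproducible
  and the winning restart's seed is reported.
* **M-step** — closed-form posterior-weighted means for the covariate-free
  blocks; damped Newton iterations (analytic gradient and Hessian,
  backtracking line search, gradient tolerance 1e-8) for the weighted
  multinomial-logit (membership) and weighted logistic (response) blocks,
  warm-started at the previous parameters.  Inside the EM loop the Newton
  refinement is capped at two steps per iteration — a partial M-step that
  still increases the expected complete-data log-likelihood, so the
  procedure is a generalized EM and the observed log-likelihood is
  non-decreasing (checked to 1e-8 slack in the property suite); a direct
  call to `m_step` runs Newton to the gradient tolerance.  Age is
  standardized inside these optimizations and coefficients are
  back-transformed to per-month units.  Coefficients are box-constrained
  to ±50 on the standardized scale, which keeps quasi-complete separation
  from driving the optimizer to infinity.
* **Convergence** — a run stops when the log-likelihood gain falls below
  `tol · (|loglik| + 1)` with `tol = 1e-8` (relative criterion, the
  convention of standard EM software for this model family; an absolute
  1e-8 criterion makes near-boundary fits crawl along a likelihood ridge
  for thousands of iterations without changing any reported quantity).
  Default `max_iter = 1000`.  The four-step pipeline retries a
  non-converged fit once with a 10× iteration budget before aborting.
* **Numerics** — response probabilities are clipped to
  [1e-10, 1 − 1e-10] *inside likelihood evaluation only*; stored estimates
  are unclipped so that probabilities estimated at exactly 0 or 1 are
  visible to the boundary count.  A class whose posterior weight falls
  below 1e-8 is frozen at its previous parameters and flagged.
* **Reporting order** — classes are relabeled by descending membership
  probability (evaluated at the sample mean age), so class 1 is always the
  largest group.  Modal classification breaks posterior ties toward the
  lower class index.

## Parameter counting and model selection

Boundary estimates (response probabilities within `boundary_tol = 1e-3` of
0 or 1, and class weights within 1e-3 of 0) do not count as free
parameters: the effective count is the nominal free-parameter count minus
the number of boundary estimates, with an empty class additionally
surrendering its whole row of response parameters.  The 1e-3 default
separates genuine boundary estimates from interior ones at two-decimal
reporting precision.

* **BIC** = −2ℓ + k·ln n with k the effective count, for non-nested
  comparisons (different K); lowest BIC wins, ties toward fewer classes.
  AIC is computed and reported but never used for selection.
* **LRT** for nested pairs (same K, covariate added):
  G² = 2(ℓ_ext − ℓ_base), df = number of covariate coefficients added.
  Caveat: the χ²(df) reference assumes the base model sits in the
  interior of the parameter space.  With several response probabilities
  estimated on the boundary and a nearly saturated pattern table (small
  n, J = 4), the extended model can gain likelihood by reorganizing the
  class profiles rather than by expressing a real age effect, so
  borderline p-values near 0.05 should be read cautiously; decisive
  values (≪ 0.001, as a strong age-on-membership effect produces) are
  robust to this.
* **Absolute fit**: G² = 2 Σ_s O_s ln(O_s/E_s) over the 2^J response
  patterns, expected counts marginalized over the empirical age
  distribution (summing each subject's pattern probabilities) when a
  covariate is present.  The nominal df (2^J − 1 − k, floored at 0) is
  unreliable when the pattern table is sparse, so the p-value is obtained
  by parametric bootstrap: simulate B replicate datasets from the fitted
  model (keeping observed ages), refit under the same restart policy, and
  use the add-one estimate p = (1 + #{G²_b ≥ G²_obs})/(B + 1), which is
  bounded below by 1/(B+1) and cannot be exactly zero.  Default B = 1000
  for reports; tests use B = 99.  Replicates whose refit fails to converge
  are re-drawn with a fresh sub-seed (capped, with the redraw count
  reported).

## The four-step pipeline

1. Fit K = 1..4 without covariates; pick K* by BIC.
2. Refit K* with age on membership; LRT against the plain K* model
   (α = 0.05).
3. Fit K = 1 with age on the response probabilities; compare BIC with the
   step-2 winner.  Lower BIC decides between "age-related strategy use"
   and "age-related accuracy growth".
4. Report the winner: response-probability table, G² with bootstrap p,
   modal classifications, and the class-by-age-group percentage table.

## The synthetic-data generator

The generator emulates the structure of a four-age-group developmental
study with four binary causal-inference items and n = 90
(23 + 23 + 23 + 21 children at ages 2–5).  Ages are drawn from per-group
normal distributions (means 30.04, 40.87, 54.39, 67.33 months; SDs 3.16,
3.56, 2.98, 2.44) truncated to the group's 12-month band, which keeps
group labels consistent with ages; the source study reports only
per-group means and SDs, so the truncated normal is this package's
modelling choice.  The `study` preset uses fixed class proportions
51/90, 27/90, 12/90 and response probabilities

|         | item 1 | item 2 | item 3 | item 4 |
|---------|-------|-------|-------|-------|
| class 1 | 1.00  | 0.67  | 0.94  | 1.00  |
| class 2 | 0.48  | 0.33  | 1.00  | 0.00  |
| class 3 | 0.00  | 0.00  | 1.00  | 1.00  |

The `age-logit` preset replaces fixed proportions with a membership logit
in age, calibrated so the class-1 share rises and the class-2 share falls
with age (crossover near 36 months; modal class 2 in the youngest group,
modal class 1 from age 3 up, small class-3 share throughout).  It is a
calibration device reproducing qualitative structure, not a
reconstruction of fitted coefficients.  The `accuracy-growth` preset is a
single class whose success logit grows at 0.06/month (≈0.34 at 30 months
to ≈0.82 at 67 months), and `one-class` is an age-free null.

What the generator does *not* emulate: within-subject dependence beyond
class membership (local independence holds exactly by construction),
item-order or counterbalancing effects, training-trial failures, and
any response process below the binary success level.  Passing recovery
and selection tests therefore show the estimator works when the model is
true, not that real children satisfy local independence.

## Identifiability caveat

With J = 4 items a 3-class model has 14 nominal parameters against 15
free pattern-table cells — nearly saturated.  The interior probabilities
and the class mix are recovered well (the simulation experiments recover
0.67, 0.33 and the boundary 0 within ±0.03 on average at n = 2000), but
the class-3 success probability on item 1 is only weakly identified: the
sample MLE systematically drifts off the generating boundary value 0
(mean absolute error ≈ 0.09 at n = 2000) because a nearby parameter
configuration fits sampled pattern tables slightly better.  This is a
property of the model family at J = 4, not of the optimizer: the drifted
solutions have strictly higher in-sample likelihood than the generating
parameters.  Conclusions about that single cell should lean on the
boundary-adjusted BIC comparison, not on its point estimate.

## Scoring and screening defaults

Raw trial codes are mapped to binary success per the intended inference
of each trial type (screening-off → the efficacious object alone;
indirect screening-off A → object Z alone; indirect screening-off B →
object Y labeled a blicket; backwards blocking → object Y *not* labeled;
non-causal association → finger press).  The indirect-screening-off-B
trial is scored on object Y's label only; a stricter variant additionally
requiring object X to be labeled a non-blicket can be configured through
the YAML scheme.  Subjects with any unscorable response are excluded
listwise.  The variability screen is one-sided (default threshold 0.05):
items whose overall success proportion is below 5% are dropped, while
near-ceiling items are retained, since a uniformly high success profile is
still informative about class structure.

## Fisher convention

The two-sided Fisher exact p sums hypergeometric probabilities of all
tables no more probable than the observed one (the common software
convention).  A doubling convention (twice the smaller tail, capped at 1)
is available via `convention="doubling"`; the two can differ at the
second decimal for skewed margins.  The Pearson chi-square is computed
without continuity correction.

## Problem sizes used in the shipped experiments

The selection experiment uses 20 datasets of n = 500 and the recovery
experiment 50 datasets of n = 2000, both with 20-restart fits — large
enough that the modal BIC choice and the mean recovered probabilities are
stable across master seeds.  The bootstrap calibration study uses 100
replicate studies of n = 90 with B = 99 and 2-restart fits (the
calibration model is well separated, so additional restarts change
nothing but runtime).
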