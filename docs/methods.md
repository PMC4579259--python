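# Methods

## Model

`trajgroup` implements group-based trajectory modeling (latent-class growth
analysis) for short ordinal panels. The population is assumed to be a finite
mixture of k latent groups; conditional on group j, subject i's scores over
the swallow-trial index t ∈ {1..7} are independent with mean structure given
by a polynomial linear predictor η_j(t) of order at most cubic. Two links
are supported:

* **Bernoulli-logit**, for three-point ordinal outcomes collapsed to a
  binary impaired category before modeling. Delay/pooling outcomes map
  {1, 2} → 1; penetration–aspiration instead collapses normal and
  penetration into 0 so that the impaired category means aspiration.
* **Censored normal (tobit)**, for the five-point piecemeal-deglutition
  score treated as continuous on [0, 4]: interior scores contribute the
  Gaussian density, scores at a bound contribute the corresponding normal
  tail probability. The residual SD σ is shared across groups — the
  conventional default for this model family; a per-group σ adds parameters
  the short panel cannot support.

Group membership is a multinomial logit on subject covariates (etiology,
dummy-coded with a configurable reference level, PD by default). Etiology
enters the membership model only, not the trajectory shapes: the scientific
summary of interest is "which trajectory does this etiology land in",
reported as membership odds ratios, not etiology-specific curves. Subjects
with missing trials contribute only their observed trials to the
within-group product, which is valid when missingness is at random given
the group.

## Estimation

The marginal log-likelihood ℓ(β, σ, θ) = Σ_i log Σ_j π_j(x_i) P(Y_i | j) is
maximized directly (no EM) by L-BFGS-B with an analytic gradient; the
mixture sum and all posterior quantities are computed with log-sum-exp so
no subject underflows. Polynomials are evaluated internally on a centered
and scaled time axis u = (t − 4)/3 ∈ [−1, 1] for conditioning, with σ
optimized as log σ; coefficients are converted back to the raw trial scale
for reporting (the leading-term Wald test is invariant to this affine
rescaling). Standard errors come from inverting the numerically
differentiated observed information at the optimum (one Hessian
evaluation); a singular information matrix is flagged and the fit is
returned without a covariance.

Initialization pre-clusters subjects by mean response into k bins, fits
each bin's polynomial on a working scale (empirical logit of per-trial
frequencies, or raw scores), and sets membership intercepts from bin
shares. Multi-start (default 3 starts) perturbs this initialization with a
seeded RNG; the best local optimum wins, ties toward the lowest start
index. Convergence uses the optimizer's relative-improvement and
gradient-norm criteria (configurable via the model spec). Fitted groups
are relabeled in ascending mean linear predictor — group 1 = lowest
impairment — and the membership logit is re-referenced to the new first
group, so the reported parametrization is always canonical.

## Model selection and adequacy

Selection is a two-step procedure. Step 1 fits k = 5 down to 1 with every
group cubic and keeps the smallest BIC = −2ℓ + p·log n, where n is the
number of subjects (an observation-count variant is exposed as `bic_nobs`;
which n the convention intends is ambiguous, so both are reported and the
subject count is primary). BIC ties within 1e−6 resolve toward fewer
groups. Step 2 keeps k fixed and repeatedly proposes reducing the order of
the group whose highest-order coefficient has the largest order and a Wald
p-value above α = 0.05 (test named nowhere in the source convention; the
standard-normal Wald test at 0.05 is the field default); a reduction is
accepted only if BIC does not increase, and rejected proposals are not
retried at the same order unless a later acceptance changes the baseline.
Step 2 therefore never increases BIC relative to the step-1 winner; k is
not revisited after pruning.

Subjects are assigned to the group with maximum posterior probability
(ties to the lower label, deterministic). Adequacy is the average posterior
probability (APP) of each group over its modal members, checked against a
configurable 0.7 threshold; empty groups are flagged as failures. Mixture
proportions are reported primarily as the sample mean of the model-implied
π (the estimated latent-group sizes), with modal shares alongside. A
practical note from the test suite: on pure-noise data a surplus-group fit
usually collapses to near-identical groups (APP ≈ 1/k) but can instead
reach a genuine boundary optimum in which a tiny extreme group captures
all-zero or all-one subjects with high APP; either way the adequacy check
fails in the overwhelming majority of replicates, but the failure mode is
not always the textbook APP ≈ 1/k picture.

Membership odds ratios are exp(θ) contrasts per non-reference group and
etiology, with 95% Wald CIs on the log-odds scale from the observed
information (reference trajectory and etiology configurable; other
reference groups are handled by linear contrast of the θ blocks).

## Observer agreement

Inter- and intra-observer agreement on the ordinal scales uses the linear
weighted kappa, κ_w = 1 − Σw·o / Σw·e with weights |i−j|/(r−1), computed
via scikit-learn's implementation behind the module surface and verified in
the tests against the direct formula. For two levels it equals unweighted
Cohen's kappa exactly. Interpretation bands are lower-inclusive:
[0.61, 0.81) substantial, [0.81, 1] almost perfect, negative values less
than chance; the conventional band table leaves [0, 0.01) unnamed, which
is reported as "no agreement beyond chance". If both raters are constant
and identical, κ is defined as 1 by convention and flagged. The pipeline
exposes the study-style screen: analyze an outcome only for etiologies
whose inter-observer κ reaches 0.61 (configurable).

## Synthetic-data generator

The generator draws etiology (multinomial over HNC/PD/DM1, default shares
73/89/43 ÷ 205), then latent group (multinomial logit on etiology), then
scores through the group's link — Bernoulli for logit, or a latent normal
clamped to the scale bounds and rounded to the integer scale for the
censored-normal outcome — and applies missingness last, from an RNG stream
separate from the score stream, so enabling missingness never changes
retained scores at a fixed seed. Three missingness patterns are modeled,
each missing-completely-at-random within pattern: cracker-trial dropout
(default rate 0.12), truncated thin-liquid runs (0.04), and fatigue dropout
ending the sequence at a uniform trial in 4–6 (0.06). The rates are
illustrative defaults chosen to yield roughly 85% complete sequences, as no
calibrated rates exist to emulate; MCAR keeps the likelihood's
missing-at-random handling valid and testable.

The default cohort design uses three logit groups — flat-low (intercept
−2.5), erratic-intermediate (cubic −2.057 + 0.802t − 0.104t² + 0.008t³,
bending at the thin→thick and thick→cracker transitions), flat-high
(intercept 2.2) — and etiology effects of |log OR| up to about 1.2. What
the generator does *not* emulate: within-trial bolus physics, rater drift
over a session, ordinal residual correlation beyond the latent group, or
informative (outcome-dependent) dropout. Tests passing on these panels
therefore certify the estimation machinery, not the clinical realism of
any particular dataset.

## Numerical choices and problem sizes

Scores at exactly a censoring bound are detected by equality, which is the
generator's convention (clamped values are exact). Empirical logits in the
initializer are clipped to [0.05, 0.95]. Degenerate inputs — subjects with
no observed trials, empty panels, non-dichotomized scores under a logit
spec — are rejected with explicit errors rather than absorbed. The
simulation-based checks use n = 600 subjects for recovery and selection
(10 seeds per design) and 200 replicates of n = 400 for CI calibration;
these sizes give binomial Monte-Carlo error comfortably inside the asserted
bands while keeping a full run to a few minutes on one CPU.

## Limitations

Dual-trajectory and time-varying-covariate models, Bayesian estimation,
zero-inflated links, kappa standard errors, and bootstrap tests for k are
out of scope. The censored-normal treatment of a 5-point ordinal scale is
an approximation inherited from the model family, not a claim about the
scale's metric properties. The `dichotomize` idempotence guard is tracked
via `DataFrame.attrs` and does not survive a CSV round-trip: re-reading an
already-dichotomized penetration–aspiration panel and dichotomizing again
would re-map aspiration to 0, so dichotomization should be applied once,
inside the pipeline, to raw scores.
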