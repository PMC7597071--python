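# Methods

This note records the statistical models, the algorithms used to fit them,
the numerical choices behind the implementation, what the synthetic-data
generator does and does not emulate, and known limitations.

## Models

For taxon h, sample j of subject i, with counts C_ij, library size T_ij,
covariates X_ij and random-effect design Z_ij (each taxon is fitted
independently; the taxon index is dropped below):

**NBMM.**  C_ij ~ NB(mu_ij, theta) with
log mu_ij = log T_ij + X_ij beta + Z_ij b_i and b_i ~ N(0, Psi).
theta > 0 controls over-dispersion (Var = mu + mu^2/theta; theta -> inf is
Poisson).  The offset log T_ij normalizes for sequencing depth; it is
omitted (`offset_policy="none"`) when the response is not a raw count.

**ZINBMM.**  A two-component mixture: with probability p_ij the count is a
structural zero; otherwise NB(mu_ij, theta) as above.  The zero
probability follows logit(p_ij) = Z*_ij alpha, optionally with a
subject-level random effect a_i ~ N(0, Phi) (a logistic mixed model).

**ZIGMM.**  The response is first transformed — y = log2(C+1) for counts,
y = arcsin sqrt(C/T) for proportions; both send raw zeros to exact zeros —
then modeled as exactly 0 with probability p_ij and N(mu_ij, sigma^2)
otherwise, with mu_ij a linear mixed model.  For log2-transformed counts a
requested library-size offset is placed on the response scale as
log(T)/log 2; offsets are rejected for proportion responses.

**Within-subject residual correlation.**  The residual correlation matrix
R_i may be AR(1) (entry rho^|lag| on the within-subject observation order)
or compound symmetry (constant rho).  Discrete observation order, not
continuous time gaps, defines the AR(1) lag; a continuous-time AR(1) is a
possible extension.  Crossed random effects and designs nested deeper than
samples-in-subjects are out of scope.

## Fitting algorithms

**Weighted LMM core** (`mbmm.lmm`).  Every outer algorithm reduces to a
Gaussian linear mixed model for a working response with prior observation
weights w: per subject, V_i = Z_i Psi Z_i' + sigma^2 W_i^{-1/2} R_i
W_i^{-1/2}.  beta and sigma^2 are profiled out in closed form (GLS and a
quadratic-form ratio); the remaining variance parameters are optimized by
L-BFGS-B on an unconstrained scale: the log-Cholesky factor of
D = Psi/sigma^2 and atanh(rho).  This keeps Psi positive semi-definite and
|rho| < 1 by construction; a D collapsing to the boundary (Psi ~ 0) is
reported in the fit's warnings, never raised.  REML is the default
criterion (ML is available and is used where a fit must be compared with
an ML-based oracle).  Two starts are used: a method-of-moments guess for
the intercept variance ratio, then a near-null start on non-convergence;
a non-convergent optimizer yields a flagged fit.  Groups of equal size are
stacked so the per-subject Cholesky/solve work runs as batched numpy
linear algebra; this is what makes screening hundreds of taxa and the
replicate studies in the test suite cheap.  Rank-deficient fixed-effect
designs have aliased columns detected by pivoted QR and dropped with a
warning.

**NBMM by PQL/IWLS** (`mbmm.nbmm`).  Starting from a Poisson GLM
(statsmodels) for mu and a moment estimate for theta, each sweep:
(1) working response z = (eta - offset) + (y - mu)/mu and weights
w = mu theta/(theta + mu); (2) weighted LMM fit of z (warm-started on the
previous sweep's variance parameters); (3) eta from the conditional
(BLUP-including) fitted values; (4) one Newton–Raphson update of theta on
the NB profile log-likelihood at the current mu, performed
multiplicatively (on the log scale) with steps clipped to +-2 and theta
clipped to [1e-3, 1e5]; a non-finite score falls back to a bounded scalar
search.  Convergence: max relative change of beta and log theta < 1e-5,
at most 50 sweeps.  mu is clipped to [1e-8, 1e8] inside the working
quantities.  Updating theta once per sweep (rather than to convergence)
reaches the same fixed point.  Standard errors are taken from the final
weighted LMM — the PQL approximation — with two-sided normal-reference
Wald p-values by default; a t reference with caller-chosen df is
available.  Non-integer "counts" (fractional abundances from some
pipelines) are accepted with a warning since IWLS needs only the
mean-variance relation.

**ZINBMM by EM-IWLS** (`mbmm.zinbmm`).  E-step: at observed zeros,
xi = p / (p + (1-p)(theta/(theta+mu))^theta), else xi = 0.  M-step, zero
part: a binomial fit with the *fractional* responsibilities as response —
the standard EM treatment of mixture membership — by IWLS (a PQL loop
through the LMM core when the zero part has a random effect); separation
triggers a ridge penalty of 1e-4 with a warning; degenerate all-0/all-1
responsibilities pin p at the clip boundary [1e-6, 1-1e-6].  M-step, count
part: NB IWLS sweeps with prior weights (1 - xi) multiplied into the
working weights, capped at 5 sweeps per M-step (nested full convergence
wastes work; the fixed point is identical).  The responsibilities enter as
prior weights, not through the working response.  Convergence: max
absolute change of all linear-scale parameters (beta, alpha, log theta)
< 1e-4, at most 100 EM iterations.  The default zero part is
intercept-only.  A response without zeros falls back to the plain NBMM
with a warning; pinning p = 0 (`force_p_zero`) delegates to the NBMM path
so the nesting is exact to the bit.

**ZIGMM by EM** (`mbmm.zigmm`).  The zero state keys on exact zeros of the
transformed response (both transformations fix 0, so this equals zero raw
abundance).  E-step: xi = p / (p + (1-p) phi(0; mu, sigma^2)) at exact
zeros, with phi the Gaussian density and mu the conditional fitted values.
M-step: the shared zero-part fit, then a weighted LMM with prior weights
(1 - xi), with sigma^2 = sum((1-xi) r^2) / sum(1-xi) — the EM-consistent
divisor, not N.  Convergence is monitored on beta, the fitted
probabilities p and log sigma^2; watching p rather than alpha lets a
zero-part logit sliding to a boundary (p -> 0 or 1) terminate cleanly.
For fixed-effects-only fits the observed-data log-likelihood is exactly
computable and is recorded per iteration (`loglik_trace`); EM monotonicity
is asserted in the tests at 1e-10 per step.  An input with no exact zeros
short-circuits to a single unit-weight LMM fit, identical to the plain
weighted-LMM path.

## Screening, summaries, plots

`screen` filters taxa by the strict rule nonzero-proportion > min_p
(default 0; a typical working value is 0.2), optionally sorts by
decreasing nonzero proportion (ties by input order), fits every retained
taxon independently — no information is shared across taxa — and catches
per-taxon exceptions as `failed` entries without disturbing any other
taxon.  Two identical runs produce byte-identical result tables.
`fixed_table` emits one row per (taxon, coefficient, part) in analysis
order; `get_fixed` slices one term across taxa; `adjust_pvalues` applies
Benjamini–Hochberg within each (term, part) across taxa (the models
themselves report raw p-values).  The forest plot draws estimate
+- 1.96 * se (a normal 95% interval; the interval level is a display
choice), colors by significance at the display alpha (default 0.05) and
annotates p-values; the heat map shows -log10(p) capped at 10 with "+"
overlaid on significant positive effects only (negative significant
effects are not marked), taxa labels truncated to 20 characters with
unique suffixing.  Both return the exact numeric objects rendered, so
tests never compare pixels.

## Synthetic-data generator

`mbmm.sim` emulates a longitudinal case-control microbiome study: a
subject-level binary group (case/control, Bernoulli 1/2), a sample-level
time on [0, 1], a subject-level standardized continuous nuisance
covariate, library sizes uniform on [5e3, 5e4], subject random intercepts
(optionally slopes), NB counts via the gamma-Poisson mixture, structural
zeros from a constant or logistic law, and unbalanced panels with the
per-subject sample count uniform on a range.  Defaults — 100 subjects x 5
samples, beta = (1.0, 0.5), theta = 2, random-intercept SD 0.5 — define
the standard study conditions used throughout the tests.  The generator
does *not* emulate compositionality, cross-taxon correlation, taxonomic
structure, batch effects, or sequencing error; passing recovery and
calibration tests on these data demonstrates correctness of the fitting
machinery under the assumed models, not robustness to real-data model
misspecification.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` size their simulation studies
so each check is statistically meaningful while the whole suite stays
quick on one core: 100-seed (tests) / 30-seed (script) recovery grids,
500 (tests) / 200 (script) null replicates for type-I error, 20 oracle
datasets of n = 200 for the degenerate NB check, 50 ZIG EM instances, and
20 Gauss–Hermite instances.

## Known limitations

* **PQL bias.**  The count-family estimates are penalized
  quasi-likelihood approximations.  On the tiny-instance oracle check
  (4 subjects x 2 observations) agreement with exact Gauss–Hermite
  maximization is within a few percent when observations are informative
  (theta ~ 20, within-subject contrast); at strong over-dispersion
  (theta ~ 2) with so few subjects the PQL-vs-exact gap can exceed 10%.
  At screening scale (tens of subjects and up) the approximation is
  excellent: the singleton-subject degenerate check agrees with the exact
  NB GLM to ~1e-6 relative, and type-I error is calibrated at the
  nominal 0.05 within [0.03, 0.08] over 500 replicates.
* **ZIGMM attenuation.**  Mixing a point mass with a Gaussian *density*
  at zero makes the zero assignment soft wherever the Gaussian branch has
  appreciable density near 0.  The MLE of this likelihood — verified
  against an independent direct-likelihood optimizer, with which the EM
  agrees — attenuates effect estimates toward zero and can drive the
  estimated p to a boundary.  This is a property of the model, not the
  optimizer; the ZIG family is also known to show inflated false-positive
  rates.  Prefer the count families when raw counts are available.
* **Standard errors** for the count families come from the final working
  LMM; no sandwich correction.  Wald tests use a normal reference by
  default, which is mildly liberal for very few subjects.
* AR(1) uses discrete observation order; unequal time gaps are treated as
  equal lags.
* Exact numerical parity with R's nlme/MASS internals (step-halving
  schedules, df conventions) is a non-goal.
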