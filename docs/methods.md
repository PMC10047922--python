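# Methods

This note records the modelling conventions, numerical choices and design
decisions behind the package, and what the simulation harnesses do and do
not demonstrate.

## Estimand and estimators

The estimand is η = E_ỹ[E_{θ|y} log g(ỹ|θ)], the out-of-sample log
density averaged over the full posterior.  All criteria are reported on
the −2·(total log likelihood) scale and decompose as
`value = −2·eta_hat_total + 2·bias_total`, where `eta_hat_total` is
Σᵢ E_{θ|y} log g(yᵢ|θ) and `bias_total` is n times the per-observation
bias correction.  This decomposition is an exact contract of
`CriterionResult`, so any criterion can be read either as a deviance or
as a bias-corrected estimate of n·η.

* **PAIC**: bias_total = tr{Jₙ⁻¹(θ̂)Iₙ(θ̂)}.  Jₙ uses the 1/n
  normalisation, Iₙ uses 1/(n−1); the asymmetry is deliberate and is what
  makes the closed-form conjugate-normal estimator come out with its
  1/(n−1) factor.  The per-observation augmented density is
  log{g(yᵢ|θ)·π(θ)^{1/n}} — each observation carries 1/n-th of the log
  prior — so that summing over observations recovers the unnormalised log
  posterior and Jₙ is its (scaled) Hessian at the mode.  An improper flat
  prior is represented as log π ≡ 0 with `prior_proper=False`; it
  contributes exactly zero to both matrices and PAIC remains defined.
* **BPIC** is implemented in its simplified plug-in form:
  η̂_BPIC = (1/n)log L(θ̂|y) − (1/n)[E_{θ|y}log π − log π(θ̂) + tr_B + K/2].
  The trace term follows the original 1/n convention for the
  outer-product matrix, i.e. tr_B = ((n−1)/n)·tr{Jₙ⁻¹Iₙ} in this
  package's matrices; with that convention the generic engine reproduces
  the conjugate closed form exactly (the prior terms and K/2 cancel
  algebraically), and the PAIC/BPIC bias ratio is n/(n−1) for every
  dataset.  E_{θ|y} log π is averaged over the draws (or taken in closed
  form when an exact backend is present).  BPIC refuses improper priors,
  whose log π(θ̂) and E log π are undefined.
* **WAIC2**: bias_total = Σᵢ Var_{θ|y} log g(yᵢ|θ) (functional
  variance).  **WAIC1** uses the standard plug-in-discrepancy form on the
  pointwise posterior-predictive density; it is provided as a convention
  and is not part of the validation studies.
* **LOO-CV** estimates η_CV = (1/n)Σᵢ E_{θ|y₋ᵢ} log g(yᵢ|θ) and reports
  bias = η̂ − η̂_CV.  `method="refit"` uses the exact leave-one-out
  posterior (conjugate backend) or a refit contract.
  `method="importance"` reuses the full-data draws with weights
  wₛ ∝ 1/g(yᵢ|θₛ).

## The two LOO weight-truncation rules

Importance weights for leave-one-out are unbounded when an observation is
influential, so the raw estimator can be dominated by a handful of draws.
Two truncation rules are provided:

* `truncation="mean"` caps raw weights at w̄·S^{3/4} (classic truncated
  importance sampling).  The cap almost never binds for well-behaved
  weights, so the estimator remains consistent for the exact
  leave-one-out expectation; this rule carries the package's
  IS-versus-refit agreement test.
* `truncation="quantile"` (default) caps the weights at the
  ⌈S^{3/4}⌉-th largest raw weight.  This is a deliberately strong
  regularisation in the spirit of the smoothed/stabilised LOO estimators
  used in practice: for models in which single observations are highly
  influential (e.g. one group per random effect), it trades a bias toward
  the in-sample estimate for a large variance reduction.  The
  hierarchical-logit experiment uses this rule; its CV column should be
  read as "regularised importance-sampling LOO", not as exact
  cross-validation.  Per-observation effective sample sizes are reported
  and a warning names any observation with ESS < 10.

## Posterior mode and derivatives

The mode maximises Σ log g + log π by BFGS, initialised at the draw with
the highest unnormalised posterior.  Strictly positive coordinates are
optimised on the log scale (clipped to ±300 to keep exp() finite during
line searches), but the mode and all downstream derivatives are reported
in the model's declared coordinates: the trace is invariant only under
affine reparameterisation, so the declared coordinates are part of the
model definition.  Convergence targets an infinity-norm gradient of 1e−8
and accepts a stalled run below 1e−5; anything worse raises, carrying the
best point found.  A strictly positive coordinate whose mode falls below
1e−3 raises a boundary warning — curvature corrections are unreliable
when the mode sits on the edge of the parameter space, which is the known
failure mode of this family of criteria (variance components at zero).

Analytic score/Hessian contracts are used when a model provides them
(both experiment models do); otherwise central finite differences with
relative steps eps^{1/3}·(1+|θₖ|) for gradients and eps^{1/4}·(1+|θₖ|)
for Hessians — the larger Hessian step controls round-off amplification
in the second difference.  Jₙ singularity is refused (with the near-null
direction named) when cond(Jₙ) > 1e10 rather than pseudo-inverted:
silent regularisation would corrupt the criterion.

Monte-Carlo standard errors for posterior averages use batch means with
20 consecutive-draw batches, which respects serial correlation in the
chains; naive i.i.d. standard errors would understate the error.

## Conjugate normal harness

Data y ~ iid N(μ_T, σ_T²) analysed as N(μ, σ_A²) with prior
N(μ₀, τ₀²); everything is closed-form, including the analytic true bias
E_y(η̂ − η) = σ_T²σ̂²/σ_A⁴ (exact for every n, independent of μ₀).  Two
printed renderings of the comparator estimators are ambiguous as typeset;
the package implements the algebraically consistent forms and keeps the
face-value renderings behind `form="printed"` for comparison:

* WAIC2 carries the 1/n that makes it equal (1/n)ΣᵢVar_{μ|y} log g(yᵢ|μ)
  exactly (Gaussian fourth-moment identity).
* The CV display retains the Gaussian normalising constant in the
  subtracted term so the constants cancel:
  b̂_CV = (Σ(yᵢ−μ̂₋ᵢ)² − Σ(yᵢ−μ̂)²)/(2nσ_A²).  Note this classic display
  evaluates the held-out density at the full-data posterior variance σ̂²;
  the generic `cv_loo(method="refit")` uses the genuine leave-one-out
  variance σ̂₍₋₁₎² and therefore differs from the display by
  (σ̂₍₋₁₎² − σ̂²)/(2σ_A²) — about 0.04 at n = 3 and O(n⁻²) thereafter.
  The honest refit is the form the importance-sampling estimator
  converges to, which is why the generic engine uses it.
* The penalized-loss estimator is implemented as
  b̂_popt = σ̂₍₋₁₎²/σ_A² with σ̂₍₋₁₎² = 1/(1/τ₀² + (n−1)/σ_A²) — the
  unique reading that converges to the true bias exactly when
  σ_A² = σ_T² and misses it asymptotically otherwise, which is the
  qualitative behaviour the replication study checks.

The replication study (`run_bias_study`) draws y per replication,
evaluates all five estimators and the realised gap in closed form
(vectorised, chunked to bound memory), and reports n·mean with
Monte-Carlo SEs per (prior scenario, σ_A², n) cell.  Each cell uses an
independent substream spawned from (seed, cell index), so extending a
grid never reshuffles existing cells.

## Hierarchical binomial-logit harness

Generating process per replication: β_{T,i} ~ N(0,1), yᵢ ~
Bin(50, invlogit(β_{T,i})), i = 1..15.  Fitted model: random-effect
logits βᵢ ~ N(μ, τ²) with hyperprior μ ~ N(0, 1000²) and τ² ~
Scaled-Inv-χ²(0.1, 10) (parameterised as density ∝
(τ²)^{−ν/2−1}exp(−νs²/2τ²); equivalently InvGamma(ν/2, νs²/2); an
InvGamma(0.001, 0.001) variant is included for prior-sensitivity
checks).  The joint parameter is θ = (β₁..β₁₅, μ, τ²) in natural
coordinates, p = 17.

**Sampler.**  Metropolis-within-Gibbs: exact normal Gibbs update for
μ | β, τ²; exact scaled-inverse-χ² (ν₀+N degrees of freedom) Gibbs update
for τ² | β, μ; vectorised adaptive random-walk Metropolis for the
conditionally independent βᵢ, tuned toward 0.44 acceptance during
warmup.  Defaults: 3 chains × (1000 warmup + 3000 iterations), thinning
1-in-5 (S = 1800 kept draws), split-R̂ computed for every coordinate with
target 1.01; a failing run is retried once with doubled iterations, and
replications that still fail are excluded and counted (more than 5%
failures aborts the experiment).  In practice the default sizing passes
the R̂ target essentially always at these data sizes.

**Observation units for the curvature matrices.**  The criteria based on
posterior averages (η̂, WAIC2, LOO-CV) use the group-level pointwise
matrix: one observation = one binomial count, matching how pointwise LOO
tools are applied to such models.  The curvature-based corrections (the
PAIC trace and BPIC) instead use the finest exchangeable unit — the
individual Bernoulli trials, n = Σnᵢ = 750 — implemented as a second
model contract over the same posterior (`trial_model_spec`).  The reason
is asymptotic: the bias theorem assumes a fixed parameter dimension with
growing information per parameter, which here is the within-group regime
(nᵢ → ∞), not the group-count regime (whose unit total equals the number
of random effects, so group-level scores are each concentrated on their
own coordinate and the trace degenerates to ≈ 2 instead of the effective
parameter count ≈ 12–13).  The two decompositions share the same total
log likelihood up to the binomial coefficients, which cancel from every
bias correction.  With the trial-level trace the correction sits at the
effective-parameter scale and the experiment reproduces the documented
error ranking.

**True out-of-sample term.**  η = (1/N)Σᵢ E_z[E_{θ|y} log g(z|βᵢ)] with
z ~ Bin(nᵢ, invlogit(β_{T,i})) at the *realised* true logits (same-unit
prediction, matching how the bias estimators are computed per observed
unit; new-unit prediction is a different estimand and is not
implemented).  Because log g(z|β) is linear in z given β, the posterior
enters only through E[βᵢ] and E[log(1+e^{βᵢ})], and the outcome
distribution is enumerated exactly over the nᵢ+1 support points — no
Monte-Carlo error from the outcome layer (a J-draw Monte-Carlo method is
kept for comparison).  Errors are reported per observation:
e = (η̂ − η) − b̂ for each criterion, with mean/SD of e, |e| and e² over
replications.

**Replication sizing.**  The error table is computed at 200 replications
(the exact outcome enumeration removes one Monte-Carlo layer, so 200
replications pin the mean errors to ≈ 0.017 nats); the conjugate-normal
checks use 10,000 replications for the unbiasedness and trace properties
and 1,000 for the misspecification cells at n = 200 — at that n the
deterministic (n−1)/n offset of the BPIC estimator is of order n·bμ/n,
and 1,000 replications keep 3 MC SE above that known finite-sample
offset, which is the correct resolution for an asymptotic-agreement
check.

**Seeding.**  One master seed; replication r uses substreams spawned as
SeedSequence(seed, spawn_key=(r,)), split again into data/sampler/outcome
children.  Replication r's results therefore never depend on the total
replication count, and swapping the τ² hyperprior leaves the simulated
datasets bit-identical (paired prior-sensitivity comparisons).

## What the harnesses do and do not show

The synthetic generators implement exactly the stated study conditions
(normal observations; binomial counts with normal random effects on the
logit scale).  They contain no outliers, no model-misspecification beyond
the variance scenarios of the normal study, no unequal group sizes and no
covariates; passing tests therefore demonstrate correctness of the
estimators and their documented small-sample behaviour under these
conditions, not robustness on messy real data.  Known limitations carried
by the method itself: regularity requires an interior posterior mode
(boundary variance components are flagged, not fixed — reparameterisation
is the practical remedy); singular or non-identified models are out of
scope; the quantile-truncated LOO is a biased (regularised) estimator by
design; and BPIC is undefined under improper priors.
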