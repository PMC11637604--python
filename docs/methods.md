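# Methods

## Model

Each trait enters a mixed "animal model" whose random effects are indexed
by *channels* — (trait, role) pairs with role *direct* (the focal
individual's own additive genetic effect) or *indirect* (the opposite-sex
partner's additive genetic effect on the focal individual's behaviour).
For records `y` stacked over one or two traits,

    V = Σ_{c≤d} G_cd (Z_c A Z_d' + [c≠d] Z_d A Z_c')
        + Σ_c V_PE,c Z_c Z_c' + Σ_t V_R,t I_t ,

with `A` the numerator relationship matrix over the pedigree, `G` the
additive genetic covariance over the active channels, one
permanent-environment (PE) variance per channel (diagonal across
individuals) and one residual variance per trait. Assumptions: additive
gene action, multivariate normality on the analysis scale, unrelated
non-inbred founders, independent residuals across records (the two members
of a dyad contribute to different records for different traits; residual
covariance between two traits scored on the same trial is fixed at zero —
with behaviour/morphology pairs never co-observed on a record it is not
identifiable, and for behaviour/behaviour pairs we adopt the weaker
assumption rather than estimate an extra parameter).

Structural rules enforced at specification time:

* morphology carries no indirect channel — a partner's genotype cannot
  change a dissected trait;
* once-measured traits carry no PE term — without repeats PE and residual
  are confounded, so PE is constrained to zero;
* bivariate models carry trait-specific intercepts only; univariate models
  for behaviours add testing order (centered covariate) and shelf
  (lower = 0, upper = 1).

All trait scores are z-transformed over the analysis sample before
partitioning; latencies are reverse-scored (multiplied by −1) before
bivariate fits and reporting so that larger values mean greater mating
motivation (own channels) or greater attractiveness (partner channels).
Reverse-scoring flips the sign of every covariance involving the latency's
channels and nothing else; this equivariance is tested.

## Restricted likelihood and its convention

    logL = −0.5 [ (n−p) log 2π − log|X'X| + log|V| + log|X'V⁻¹X| + y'Py ]

The constant is chosen so the value equals the exact Gaussian log-density
of error contrasts `B'y` for an orthonormal basis `B` of the null space of
`X'`; the test suite holds the implementation to that equality at 1e-8 and
to invariance under `y → y + Xc`. LRTs never depend on the constant.

## Estimation

The covariance parameters are mapped to an unconstrained scale: the genetic
block through its Cholesky factor with log-diagonal (log-Cholesky), PE and
residual variances through logs. A single pinned genetic covariance (needed
for correlation LRTs) is realized exactly by permuting the pinned pair to
the front of the block, where one zeroed Cholesky entry pins the
covariance.

The maximizer is average-information (AI) REML: Newton ascent using the AI
matrix mapped through the reparameterization Jacobian as a Gauss-Newton
Hessian, with backtracking line search, followed by an L-BFGS-B polish with
analytic gradients (convergence: relative logL change < 1e-8, parameter
change < 1e-6, gradient tolerance 1e-7). A derivative-free simplex start
was tried first and dropped: at n ≈ 1600 records its hundreds of O(n³)
evaluations dominated runtime without changing the optimum (AI + polish
reach the same logL to ≤ 2e-8). `fit(..., restarts=k)` runs k
seed-jittered starts and keeps the best; the pipeline uses one start but
warm-starts every bivariate fit from the univariate solutions and every
constrained fit from the full solution.

Boundary handling: variances may collapse to (numerically) zero; estimates
below 1e-6 and correlations within 1e-4 of ±1 are flagged as boundary.
Correlations whose parent variance is boundary-pinned are reported NA with
a flag — they are undefined and untestable, which is exactly the situation
of a trait with no detectable genetic variance in either channel.
Standard errors are from the inverse AI matrix at the optimum; correlation
SEs follow by the delta method. When optimizer noise lets a reduced fit
edge above the full fit near a boundary, the full model is refit from the
reduced solution before the LRT is formed (`refit_if_beaten`), restoring
the nesting inequality; LRT statistics within 1e-3 of zero from below are
clipped to zero.

## Significance conventions

* Variance tested on its zero boundary: p = 0.5 P(χ²₁ ≥ LRT) for LRT > 0
  and p = 0.5 at LRT = 0 (the 50:50 χ²₀/χ²₁ mixture; the point mass
  contributes through a strict inequality).
* Covariance/correlation (interior null): p = P(χ²₁ ≥ LRT), which is 1 at
  LRT = 0. Published tables in this literature sometimes print p = 0.50
  for correlation rows with χ² = 0.00, which a pure df = 1 convention
  cannot produce; this package keeps the two conventions distinct and
  documents the discrepancy here rather than blending them.
* No multiple-testing correction anywhere, by design: the analysis trades
  type-I for type-II error control across its many related tests.

The calibration experiment for the mixture test pins COV_Am,Af to zero in
both the full and the reduced model, so that the null constrains exactly
one variance on its boundary — the setting in which the 50:50 mixture is
the correct reference. Dropping a variance *and* its covariance in one step
is a two-parameter boundary test for which the mixture is mildly
anti-conservative (~8% empirical at α = 0.05 in pilots).

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not cricket biology: breeding values flow down the pedigree (founders
i.i.d. MVN(0, G₀); offspring = mid-parent + Mendelian deviation scaled by
0.5 − 0.25(F_s + F_d)); dyadic trait values add fixed effects, the focal
individual's direct genetic + PE effects, the partner's indirect genetic +
PE effects, and Gaussian residuals; body mass repeats per trial; mandible
and testis are measured once. Traits are generated directly on the z scale
(the analysis scale); raw latencies, censored trials (pairs that never sang
or mounted), non-Gaussian tails and selection are *not* emulated, so
passing tests demonstrate correct inference under the model's own
assumptions, not robustness to their violation.

The study-scale preset fixes the design at 35 sires × 2 dams, family
failure rate 4/70 (≈ 66 surviving full-sib families), 16 offspring per
family, and a nursery sex ratio of P(male) = 310/1057 so that ≈ 310 males
and ≈ 747 females are available — reproducing 826 assays at 1–3 trials per
male (one per day) with females drawn without replacement and reused only
once the pool is exhausted (≈ 80 reuses). Default variance structure, on
the z scale: each behavioural channel V_A(direct) = 0.15,
V_A(indirect) = 0.10, COV = 0.05, PE = 0.10, V_R = 0.60; morphology
strongly heritable (V_A = 0.4–0.5); guarding distance carries *zero*
genetic variance in both channels, providing the no-signal scenario in
which correlations become untestable. Two cross-channel correlations of
0.6 are planted: female attractiveness (indirect channel of male singing
latency) with male testis size — negative on the raw latency scale, hence
positive after reverse-scoring — and male body mass with mandible size.
When an unlucky small-scale replicate realizes fewer males than the assay
target presumes, the generator caps assays at 3 × males with a warning
rather than failing.

## Experiment sizes

Chosen as the package's own defaults for its simulation experiments:
parameter recovery uses 30 replicates of the 15-sire scaled design (~354
assays each); LRT calibration uses 200 null replicates (power: 30) of a
14-sire × 2 × 14 design with 500 assays, where the boundary asymptotics
are accurate; the planted-correlation recovery averages study-scale
replicates because a single study-sized dataset estimates a genetic
correlation with SE ≈ 0.2–0.3 — at that precision per-replicate
significance of a true r = 0.6 occurs in only ~60% of replicates (pilot:
7/12), so claims are made about replicate means, not single runs.

## Known limitations

* Dense linear algebra throughout: fine to a few thousand records; the
  sparse A⁻¹ / mixed-model-equation path exists in the pedigree module but
  is not wired into the likelihood.
* At most one genetic covariance can be pinned per constrained fit (all the
  analysis's tests need exactly one).
* AI-based SEs are curvature approximations; near boundaries they can be
  unstable and are reported NaN rather than extrapolated.
* Joint fits are limited to two traits; the full correlation table is
  assembled from bivariate fits, as is standard practice for this design
  size.
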