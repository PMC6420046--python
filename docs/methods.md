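# Methods

This note documents the statistical model, the estimation conventions and
the simulation design behind `huntsurvey`, including the choices made
where the underlying theory leaves the implementation open.

## Estimands and design frame

The target is the total hunting bag t = Σ_{k∈U} y_k = N·ȳ of a finite
population U of N hunters.  All expectations and variances are
*design-based*: they are taken over the randomness of sampling and of the
nonresponse mechanism, conditionally on one fixed population.  In the
Monte Carlo experiments the truth for a bias index is therefore the
realized population mean ȳ, not the superpopulation mean μ.

## Superpopulation model

Bags are generated i.i.d. from a hurdle-at-zero Poisson model:
Pr(Y=0) = p and Pr(Y=y) = φ e^{−λ} λ^y / y! for y ≥ 1, with
φ = (1−p)/(1−e^{−λ}).  Mean and variance are μ = φλ and
μ₂ = φλ(1+λ) − (φλ)².  Given a target mean, λ is recovered from
μ = λ(1−p)/(1−e^{−λ}) through the Lambert-W closed form
λ = W₀(D e^D) − D with D = μ/(p−1); a Brent bisection on the original
equation backs the closed form up whenever the W evaluation is
numerically borderline, and the two must agree to 1e−8.  The equation has
a positive root only when μ > 1−p (every positive bag is at least 1);
infeasible inputs raise a domain error naming the violated condition.

Reference parameterization: p = 0.955, λ = 7, hence μ ≈ 0.315 — the order
of magnitude of national per-hunter bags for a duck species with a large
inactive-hunter fraction — and N = 10 000, a typical regional hunter
population.  The zero-truncated Poisson part is sampled by exact
inverse-CDF transform, so generated populations follow the model pmf
exactly up to RNG quality.

## Sampling designs

All phases use SRSWOR.  Non-integer target sizes n_si = n_m,i−1·ν_i are
materialized by randomized rounding — ⌊α⌋+1 with probability α−⌊α⌋ —
whose expectation is exactly α; deterministic rounding would bias the
expected sample sizes across replicates, so the rounding is applied at
every phase of every replicate.  Unit identity is the 0-based index into
the population array.

## Estimators and conventions

* **Two-phase (Hansen–Hurwitz).**  ȳ_HH = (n_r1 ȳ_r1 + n_m1 ȳ_r2)/n_s1.
  Theoretical variance (1/n_s1 − 1/N)S² + (1/n_s1)(1/ν_m − 1)W_M S_M²,
  and a nonnegative variance estimator that is design-unbiased under full
  follow-up response.  All dispersions use the 1/(N−1) convention.
* **L-phase (El-Badry).**  The canonical point estimator is the
  *sample-size form*, in which the design fractions are replaced by the
  realized ratios n_sj/n_m,j−1; the ν-form is retained only as a
  cross-check under exact integer sizes, where the two coincide.
* **Three products, three names.**  The literature overloads one symbol
  for the forward-fraction product Π ν_j (stratum weights), the
  inverse-fraction product Π 1/ν_j (theoretical variance) and the
  size-ratio products used by the point and variance estimators.  The
  code keeps them as separately named running products; the variance
  estimator additionally maintains backward recursions
  t_i = Σ_{r_i} y + (n_mi/n_s,i+1) t_{i+1} (and z_i for squares).
* **Reduction identities.**  With L = 2 the EB point and variance
  estimators equal their HH counterparts to machine precision; these
  identities are enforced in the test suite at 1e−10 relative tolerance,
  and exhaustive design-space enumeration on toy populations confirms
  E(t̂) = t and E(V̂) = V(t̂) exactly — including under randomized
  rounding of the subsample size.

### Degenerate sizes

A phase with no respondents contributes a zero term to the point
estimator (its mean is never evaluated).  Variance estimation requires
n_s1 ≥ 2 and at least two contributing units behind every dispersion term
actually used; otherwise the variance estimate is NaN accompanied by a
`DegenerateSizeWarning` — never a silent zero, so downstream averages
cannot be quietly deflated.  If a wave exhausts the nonrespondents
(n_mi = 0), later phases are vacuous and only realized terms are summed;
a chain that collapses to a single fully-responding phase falls back to
the SRSWOR variance estimator, which is the ℓ = 0 limit of the general
formula.

### Last-phase nonresponse

The estimators are unbiased only under a 100% response rate at the final
interview phase, and the formulas are written under that assumption
(n_rL = n_sL).  When simulating *imperfect* last-phase response the
package scores final-phase nonrespondents as null harvest: the last-phase
mean becomes the respondent total divided by the full sample size n_sL
(`impute_last_phase_nulls`).  This is the field-realistic fallback —
consistent with nonresponse being driven by null bags — and it is what
produces the characteristic behaviour of the strategy: a downward bias
that grows with π_m(L), shrinks as the number of phases grows, and is
*largest* at π_z = 0 (where the imputation is most wrong, because
last-phase nonrespondents are then missing completely at random) while
nearly vanishing at high π_z (where they really do have null bags).
Feeding the plain respondent mean in at the last phase instead produces a
small *upward* bias and none of these effects.  The estimator functions
themselves stay literal to the formulas; the imputation is an explicit,
separately testable step applied by the Monte Carlo driver.

## Nonresponse mechanism

For a pool of n units the mechanism draws N_M (E = nπ_m) nonrespondents
of which N_Z (E = nπ_zπ_m) are null-bag-driven: Z is an SRSWOR subset of
the pool's zero-bag units, respondents R are an SRSWOR subset of the pool
minus Z, and M = pool − R ⊇ Z.  Undercovering the zero stratum inflates
E(ȳ_r) by the factor 1/(1 − π_zπ_m); π_z = 0 gives MCAR.  Three
implementation choices:

* **Feasibility clipping.**  N_Z is clipped to min(N_M, #zero-bag units);
  clipping events are counted and reported so users can detect regimes
  where the clip distorts E(N_Z).  At the reference settings they do not
  occur.
* **Order of draws.**  N_M before N_Z, with independent rounding draws.
* **Fresh partitions per phase.**  Respondence is redrawn independently
  on every pool, so a null-driven nonrespondent of wave j may respond at
  wave j+1.  The alternative — persistent reluctance across waves — is a
  plausible behavioural model but a different mechanism; it would deepen
  the bias at later phases and is deliberately not implemented.

## Monte Carlo engine

One population per scenario, held fixed across replicates.  Replicate
independence and reproducibility come from PCG64 streams keyed as
SeedSequence(master_seed, spawn_key=(1, cell_index, replicate_index)),
with the population on spawn_key=(0,); identical configurations are
bit-identical.  Bias indices are r = mean(ω̂)/ω with the Monte Carlo
standard error reported alongside; the variance analogue
r_V = E(V̂)/V_MC uses a delta-method SE that accounts for noise and
covariance in both numerator and denominator.

Default replicate counts follow the reference experiments (1 000 for the
two-phase table, 10 000 for the multiphase curves, 10⁵–10⁶ for the
surface and variance studies); the shipped tests and the acceptance
script run 1 000–50 000 replicates per cell, the package's desk-scale
choice, with comparisons through 99% MC confidence bands plus a fixed
0.01 allowance for the variability induced by conditioning on a single
population realization.

## What the simulations do and do not show

The generator emulates the zero-inflated, overdispersed count structure
of real single-species bag data and the null-harvest response behaviour.
It does not model response error (prestige bias, recall error, species
misclassification), coverage error, correlated response behaviour within
households or clubs, or persistent wave-to-wave reluctance.  Passing
tests therefore demonstrate the design-based properties of the
estimators under the stated mechanism, not robustness to those other
error sources — which no nonrespondent-subsampling design addresses.

## Known limitations

* Cost/precision optimization of the fractions ν_i is out of scope.
* No confidence-interval construction beyond standard errors.
* The variance estimator is exactly unbiased only under full last-phase
  response; under imperfect response it underestimates (r_V < 1), which
  the engine quantifies but the package does not correct.
* Exact reproduction of any particular published realization is not
  possible without its RNG streams; agreement is statistical, through MC
  confidence bands.
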