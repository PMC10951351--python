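# Methods

`doserr` is a simulation laboratory for studying how dose measurement
error — and corrections for it — distort excess-relative-risk (ERR)
estimation in grouped Poisson regression, in the setting of radiation
epidemiology cohorts grouped by dose (the synthetic cohort is shaped
like the Life Span Study leukaemia data: five bone-marrow dose groups,
heavily weighted toward low dose).

## Dose error model

True and surrogate doses for individual *i* (dose group *k*) in
sub-simulation *j* are lognormal perturbations of the group's central
dose estimate D_cent,k:

    D_true,ij = D_cent,k · exp[−(σ²_sB + σ²_uB)/2] · exp[σ_sB ε_j + σ_uB δ_ij]
    D_surr,ij = D_cent,k · exp[−(σ²_sC + σ²_uC)/2] · exp[σ_sC μ_j + σ_uC κ_ij]

with ε, δ, μ, κ i.i.d. standard normal.  The subscripts are s/u =
shared/unshared and B/C = Berkson/classical; the leading factors make
every dose's expectation equal to D_cent.  Shared draws are common to
all individuals of a sub-simulation, producing between-individual dose
correlation with closed form (e^{σ²_s}−1)/(e^{σ²_s+σ²_u}−1), which the
package also estimates empirically (average sample Pearson correlation
over up to 500 seeded random individual pairs; the pair cap keeps the
estimator O(pairs·m) instead of O(n²·m)).  With both Berkson SDs zero
the model is purely classical (true dose = central estimate); with both
classical SDs zero it is purely Berkson.

The four standard-normal fields are drawn from four independently
seeded streams, so changing one σ can never perturb another component's
draws.  This gives two structural invariants that the tests assert
byte-for-byte: surrogate doses are independent of the Berkson σ values,
and every estimator that uses true doses is invariant to the classical
σ values.

## Cohort simulation

One *meta-simulation* holds m sub-simulations of doses (default 1000)
and a single draw of N = 250 cancer cases.  Each individual's relative
risk RR = 1 + αd + βd² is averaged over the m true-dose realizations
(the expectation of RR over dose uncertainty, not the RR of the mean
dose — the two differ in the quadratic term; the choice is switchable in
principle but the averaged-RR form is used throughout), scaled by
exp(κ) so the case probabilities sum to one, and the N cases are drawn
multinomially over dose groups with probabilities proportional to the
within-group sums (equivalent to individual-level Bernoulli sampling
conditioned on the total, and far cheaper).  The case distribution is
constant across the sub-simulations of its ensemble.

Default risk models: linear-quadratic α = 0.25/Gy, β = 2/Gy², and
linear α = 3/Gy.  Default groups: boundaries 0–0.07 / 0.08–0.19 /
0.20–0.99 / 1.00–2.49 / ≥2.50 Gy, central doses 0.03, 0.12, 0.5, 1.5,
2.0 Gy (the top group pinned at 2 Gy, the rest near plausible
person-year-weighted means), 10,000 individuals split
0.70/0.15/0.10/0.04/0.01 across groups, person-years proportional to
group size.  All of this is configurable through `DoseGroupSpec` and
the steering files; coverage and bias results at non-zero error are
quantitatively sensitive to the group composition, so cross-study
comparisons should hold it fixed.

## The statistical core

Fitting uses the grouped Poisson likelihood with rates
T_g·exp(κ)·(1 + αd_g + βd_g²), offsets T_g person-years, and the hard
constraint 1 + αd + βd² > 0 (log-likelihood −∞ outside, so samplers and
optimizers reject naturally).  The likelihood constant convention is
Σ y log μ − μ with no log y! term; it cancels from every quantity used
downstream (MLEs, profile intervals, AIC differences and AIC softmax
weights).

The intercept is concentrated analytically (exp(κ̂) = N / Σ T_g R_g),
reducing fits to 1–2 dimensional damped Newton iterations with analytic
gradients and Hessians, vectorized across dose-vector batches — this is
what makes per-ensemble refits of 1000 dose vectors (for FMA and the
ERC interval inflation) cheap.  Profile-likelihood 95% intervals are
found where the profile deviance rises by χ²₁(0.95) = 3.841, by
geometric bracketing from the MLE and bisection (deviance tolerance
1e−5), re-maximizing the nuisance coefficient at every trial point with
a warm-started 1-D Newton.  Sides whose deviance never reaches the
threshold are reported open (±∞) and flagged; for the linear form a
side can stop at the positivity boundary, also flagged.  Non-converged
fits are flagged, never silently returned.

AIC counts κ as a free parameter (3 parameters linear-quadratic, 2
linear); only AIC differences matter anywhere.

## Estimators

* **Unadjusted** — fits the surrogate group-mean dose vector of the
  first sub-simulation.  Averaging surrogate means over all
  sub-simulations would cancel the shared classical factor e^{σ_sC μ}
  that unadjusted regression is supposed to suffer from, so a single
  designated realization is used (seeded, configurable).
* **Regression calibration (RC)** — fits the across-realization mean of
  the true-dose group means.
* **Extended regression calibration (ERC)** — RC's point estimate; the
  interval is widened for shared dose uncertainty by refitting every
  dose realization, taking the between-realization SD of each
  coefficient, combining it with the within-fit SD (profile half-width
  / 1.96) by a law of total variance, and scaling the profile interval
  about the estimate by the resulting factor.  At zero Berkson error
  all realizations coincide and ERC reduces exactly to RC; with m = 1
  the inflation is skipped and flagged.  This construction satisfies
  the observable constraints on ERC used here (equality with RC at zero
  Berkson error, widening under shared error); it is isolated behind
  its method tag so a different interval construction can replace it.
* **MCML** — maximizes the Monte Carlo likelihood (1/m) Σ_k L_k(θ)
  (average of likelihoods, log-sum-exp stabilized), with profile
  intervals of the same averaged likelihood.  Nelder–Mead on the 2–3
  free parameters, started from the RC fit.
* **Quasi-2DMC with BMA** — see below.
* **FMA** — fits every dose vector by ML; recovers per-coefficient SDs
  from the profile intervals as min(half-width)/1.96 (when one side is
  open the finite side's half-width is used and counted); weights
  exp(−AIC_j/2)/Σ exp(−AIC_k/2); draws k = 100 normal samples per fit
  per coefficient, each carrying weight w_j/k; the weighted mean is the
  central estimate and the weighted 2.5/97.5 centiles (smallest sample
  whose cumulative weight reaches the level) the interval.  Per-vector
  fits that fail to converge are excluded and counted.

## The quasi-2DMC BMA sampler

The m dose-vector realizations are treated as competing models with
mixture weights p_j parameterized by a softmax over latent λ_j
(j = 1..m−1; the last weight is the remainder).  All parameters (α, β,
κ, λ) have N(0, 1000²) priors.  Metropolis–Hastings alternates
(a) single-site random-walk updates of κ, α, β (proposal SDs 0.2, 1, 1;
scan order κ, α, β) and (b) block updates of λ in consecutive blocks of
10 with a single joint accept per block (proposal SD 2 per component;
trailing partial block allowed).  Two chains are run (the second starts
2 proposal-SDs above the first on each coefficient), 1000 burn-in and
1000 kept draws each; summaries are posterior means, equal-tail 95%
intervals from the pooled 2.5/97.5 centiles, the Brooks–Gelman–Rubin
potential scale reduction factor √[((n−1)/n·W + B/n)/W] per parameter,
and acceptance rates.  A fit is flagged non-converged when any BGR
exceeds 1.03 or a main-parameter acceptance rate leaves [5%, 80%];
flagged fits are excluded (and counted) from coverage summaries.

The dose-response update conditions on the weights through the pooled
average of the per-realization log-likelihoods, (1/m)·Σ_k log L_k(θ)
at the symmetric point of the weight prior (the λ update feeds the
posterior weight summaries, not the θ conditional).  This pooling is
what defines the estimator's characteristic failure: a single (α, β, κ)
must compromise across dose vectors that differ by a large shared scale
factor, which attenuates the fitted curvature toward zero, inflates the
linear coefficient in compensation, and leaves a deceptively tight
posterior.  Under heavy shared Berkson error the equal-tail intervals
then all but never cover the true coefficients, while at zero Berkson
error all realizations coincide and the sampler reduces exactly to a
single-model Bayesian fit.  The alternative of conditioning θ on the
sampled weights through the mixture itself makes the posterior
concentrate on single dose-vector realizations and mix along the
coefficient-rescaling ridge, which produces wide, roughly calibrated
intervals — behaviour incompatible with the tight, badly-biased
linear-quadratic posteriors this estimator family is reported to
produce (most tellingly: under purely shared error any
single-realization posterior would restore the full curvature, which
is not what is observed).  The linear-mixture log-likelihood
log Σ p_k L_k is still exposed (`mixture_log_likelihood`) and equals
the MCML objective at uniform weights.

Note the λ posterior is barely informed (a single cohort cannot
distinguish 1000 weight components); over a finite run the softmax
weights drift by diffusion, so which components carry weight in the
posterior-mean summary is a seeded Monte-Carlo accident — the tests
assert exactly this exchangeability.

## Study orchestration and seeding

`run_study` crosses scenarios × risk models × n_meta ensembles ×
methods and aggregates: 95%-interval coverage per coefficient
(converged fits only, exclusions counted), ensemble-mean coefficients,
and percent ERR bias
100·[(α_mean·D + β_mean·D²)/(α·D + β·D²) − 1] at prediction doses 0.1
and 1 Gy.  Seeding is hierarchical from (master seed, risk-model index,
Berkson σ pair, ensemble index) with named child streams; classical σ
values are deliberately excluded from the key so that scenarios
differing only in classical error share every draw — making the
"classical error moves only the unadjusted fit" property exact, not
statistical.  Missing cells (zero converged fits) are reported and the
run continues.

Default study sizes follow the study design (n = 500 ensembles,
m = 1000 sub-simulations); the bundled tests and the acceptance script
run the well-specified-regime coverage checks at n = 500 with a single
dose realization (exact at zero Berkson error, where every realization
equals the central doses) and the model-averaging scenario at n = 100
ensembles with the full m = 1000 — problem sizes chosen so the whole
suite replicates at desk scale.

## Numerical choices

* Newton steps are damped by backtracking until the positivity
  constraint and monotone ascent hold; non-negative-definite Hessians
  fall back to scaled gradient ascent.  Convergence is a gradient-norm
  tolerance of 1e−8·(1+N).
* Log-sum-exp stabilization everywhere a mixture or softmax appears;
  softmax outputs renormalized to sum to one exactly.
* Group means of identical doses are exact only to float summation
  order; degeneracy tests compare at 1e−14 relative.
* The sampler caches per-realization log-likelihoods within an
  iteration and updates the λ-block sums incrementally (blocks are
  disjoint, so candidate deltas are precomputed vectorized; only the
  running totals are sequential).

## Known limitations

* The ERC interval construction is a documented stand-in satisfying
  the properties observable here, not a replication of the original
  derivation; results for ERC at non-zero Berkson error depend on it.
* The synthetic cohort's group composition stands in for unavailable
  source values; quantities that trade interval width against shared
  dose spread (notably unadjusted-fit coverage, and FMA/BMA coefficient
  magnitudes at high shared error) shift by a few points under
  different plausible compositions.
* No covariates, stratification, time-dependent rates, overdispersion,
  or non-lognormal error families; doses are group-centred throughout.
* Per-fit BGR thresholding at 1.03 with 1000 kept draws is strict;
  heavy-error scenarios flag an appreciable fraction of fits, which are
  excluded from coverage (and counted) rather than imputed.
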