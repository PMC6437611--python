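# Methods

`rdspse` estimates the size N of a hidden population (female sex workers,
men who have sex with men, people who inject drugs, ...) from a single
respondent-driven sampling (RDS) survey, using the successive-sampling
population size estimation model with joint imputation of each
participant's latent *visibility*.

## Model

**Sampling model.** RDS recruitment is approximated by successive sampling:
units are drawn sequentially without replacement with probability
proportional to a latent positive integer visibility u_i.  Writing
u_(1)..u_(n) for the visibilities in enrollment order, S_k = Σ_{j≥k} u_(j),
and W for the total visibility of the N − n unsampled units, the
probability of the observed order is

    Π_{k=1..n}  u_(k) / (W + S_k).

Because the n sampled units are an anonymous subset of N exchangeable
units, the marginal likelihood for N carries the factor N!/(N−n)!; without
it the order probability alone always prefers the smallest N, with it the
likelihood flattens as N grows, as it should (a small sample from a large
population carries almost no information about N beyond the degree
distribution).  In the equal-visibility case the two terms cancel exactly
and the posterior equals the prior — the model correctly reports "no
information" under simple random sampling.

**Superpopulation.** Visibilities are i.i.d. draws from a zero-truncated
count distribution on {1, 2, ...} with unknown mean μ and SD σ —
Conway-Maxwell-Poisson (CMP) by default, negative binomial as an
alternative.  The CMP pmf is λ^x/(x!)^ν/Z(λ, ν); the infinite normalizer is
truncated when the relative term falls below 1e-12.  The sampler works in
(log λ, log ν) and reports the induced (μ, σ).

**Measurement error.** A reported degree d_i (the "seen in the past month"
answer when available, else the broader count) is modeled as CMP with mean
τ·u_i and dispersion ν = 1/ρ: τ > 1 is proportional over-reporting, ρ
scales the relative error (Var(d|u) ≈ ρτu; ρ = 1 is Poisson-level noise,
ρ → 0 the deterministic limit d = round(τu)).  Missing degrees keep their
unit in the model; the measurement term is simply dropped and the
visibility is imputed from the superpopulation and the order alone.
Setting `impute_visibility=False` pins u_i = max(d_i, 1), recovering
SS-PSE without imputation.

**Priors.** N has a discrete prior on {n..max_N}, by default induced by a
Beta(1, β) law on the sample fraction n/N, exactly discretized per integer
N, with β solved (bisection on the cdf at the prior median) so the grid
median equals the expert prior median; the result has the heavy right tail
typical of elicited size priors.  `max_N` defaults to
max(20·median, 10·n).  Flat and discretized log-normal families are also
available.  Hyperpriors are weakly informative: μ ~ log-normal centered at
the sample mean reported degree (log-scale 0.7); σ ~ half-normal with
scale 2·SD(d)+1; τ ~ log-normal centered at 1 (log-scale 0.5);
ρ ~ half-normal(1), supported on ρ ≥ 0.02 so the CMP mean→λ solve stays in
its smooth regime (ν ≤ 50).  The (μ, σ) hyperpriors are evaluated at the
moments induced by (λ, ν) without a Jacobian correction — i.e. they define
a valid prior directly on (λ, ν); this keeps the MCMC inner loop free of a
2-D numerical Jacobian.

## Posterior computation

Metropolis-within-Gibbs with five blocks per sweep:

1. **Visibilities** — per-participant integer random-walk proposals (step
   span ~0.6·√d_i), with the suffix-sum denominators updated incrementally
   (numba kernel, O(n²) per sweep).
2. **Superpopulation (λ, ν)** — bivariate Gaussian random walk on the log
   scale.
3. **Measurement (τ, ρ)** — bivariate Gaussian random walk on the log
   scale; each proposal re-solves λ(τ·v, ν) for all candidate visibilities
   by a vectorized damped Newton iteration (d mean/d log λ = variance).
4. **Unsampled total W.**  W is a single latent scalar — the unsampled
   units enter the likelihood only through it.  Its conditional
   distribution given (N, θ) is the N−n-fold convolution of the
   superpopulation.  Two regimes:
   * *small grids* (max_N − n ≤ 60): W is kept discrete and re-proposed
     from exact sums of superpopulation draws, with a 25-candidate
     multiple-try step (the proposal density cancels from the weights).
     This is the regime of the exact-enumeration checks.
   * *large grids*: W is represented non-centrally as
     W = (N−n)μ + √(N−n)·σ·Z with Z standard normal truncated to |Z| ≤ 6.
     The truncation matters: the exact sum of m visibilities ≥ 1 keeps
     |Z| < 6 with probability ≈ 1−1e-9 but has far lighter tails than the
     Gaussian, whose left tail would otherwise place mass at W < N−n —
     impossible when every visibility is at least 1 — and let the chain
     collapse toward N ≈ n.  Z moves by an adapted random walk.
5. **Population size N** — integer random walk on the prior grid.  In the
   non-centered regime W slides along the (N, W) ridge automatically at
   fixed Z (this is what makes the chain mix: W is pinned by the data to a
   window far narrower than its conditional prior spread, so independence
   redraws of W stall); on small grids the W redraw is multiple-try.

Proposal scales adapt toward 30–40% acceptance during burn-in only.
Defaults: burn-in 2000, 5000 retained draws, thinning 2.  Chains are
bit-reproducible under a fixed `rng_seed`.  Posterior quantiles use type-7
(linear interpolation) throughout — the median of draws 1..100 is 50.5
under this convention.

**Validation.** Three independent oracles back the sampler: (i) summed
order probabilities equal 1 exactly for every enumerable population;
(ii) on tiny grids the posterior over N matches exact enumeration over all
unsampled visibility assignments (total variation < 0.01 in the checks,
both with and without measurement error); (iii) with θ fixed the posterior
matches direct quadrature over Z at survey scale.

## Synthetic data generator

The generator *is* the model's null case, by design: populations draw
i.i.d. visibilities from the configured superpopulation, recruitment is
simulated at the successive-sampling approximation level (no explicit
social graph), seeds are the first PPS draws (they are "well networked" by
construction; a top-k mode exists for robustness experiments), recruiter
links are attached afterwards to earlier enrollees with open coupons so
chain plots and waves work, and reports come from the same CMP
measurement model, optionally heaped to multiples of 5 or 10.  Defaults
emulate the study conditions of the Armenia surveys: target samples of
100 (small city) or 300 (capital), ≤3 coupons, 4 seeds, visibility mean
10 and SD 5, unbiased reports (τ = 1) with Poisson-level noise (ρ = 1),
no heaping.  The misreporting magnitudes are conventions — the surveys
report none — chosen once as what self-reported network sizes plausibly
carry.

What the generator does **not** emulate: network topology (homophily,
clustering, bottleneck geometry beyond the explicit multi-component
switch), differential recruitment behavior, coupon expiry. Passing tests
therefore show correctness *under the successive-sampling approximation*,
not robustness to its violation in real networks.

A two-component mode with `cross_component_rate=0` reproduces the
bottleneck scenario: recruitment can never leave the components the seeds
landed in, and the fitted N then refers to the reachable subpopulation
only.

## Calibration findings

The acceptance script (`scripts/acceptance.py`) runs a simulation study at
the survey's own conditions — N = 1000, n = 300, the prior median placed
at the truth, reduced chains — and reports the 90% credible-interval
coverage and the median relative bias of the posterior median.  Two
properties of the *model itself* (reproduced by exact quadrature with all
nuisance parameters known, so they are not sampler artifacts) are worth
stating plainly:

* **Coverage is conservative** when the prior median sits at the truth:
  with weak order information the posterior reverts to the prior, whose
  median is the truth, so 90% intervals cover nearly always.
* **The posterior median is biased upward** (on the order of +15–30% at
  these conditions): the likelihood flattens for large N, so the posterior
  inherits the prior's heavy right tail; measurement noise (ρ = 1)
  amplifies this by diluting the depletion signal.  This is the behavior
  of the published method's own design (skewed prior, median point
  estimate), not a defect introduced here; the script reports whatever the
  run computes.

The degree-inflation factor τ is only partially identified — the order
likelihood is exactly scale-free in the visibilities — so its posterior
blends the count-family shape information with the prior centered at 1;
recovery of τ ≠ 1 is slow (long burn-in) and visibly shrunk toward 1.

## Numerical choices and degenerate inputs

* CMP series truncation at relative term 1e-12; mean→λ by bisection to
  1e-8 (public API) or vectorized damped Newton (inner loop).
* Superpopulation moment matching by hybrid root-solve on the truncated
  grid; σ = 0 is a point mass; infeasible moments (μ < 1, underdispersed
  negative binomial) raise.
* Enrollment order is the time axis; calendar dates are optional metadata,
  ties broken by file order and logged.
* Reported degree 0 is legal data; visibility support starts at 1.
* Impossibly high degrees are never truncated at read time; a configurable
  cap only flags them.
* "Between" in the Great/Good/Okay/Bad rules is inclusive at both
  endpoints (ties get the better verdict).
* The degree-trend label uses the OLS slope of effective degree on
  standardized enrollment order with a two-sided permutation test (2000
  permutations, α = 0.05); all-constant degrees short-circuit to
  ("constant", p = 1).
* Samples below n = 20 are refused, below 50 warned about.

## Known limitations

* The normal approximation for W is crude when the posterior puts mass
  very near N = n on a large grid (N = n itself is excluded there); the
  exact regime handles small grids.
* τ and μ trade off almost freely; interpret τ's posterior as
  prior-informed, not data-determined.
* Multiplier inputs take an externally computed survey proportion; RDS
  weighting of that proportion is out of scope.
* No graph-based recruitment simulation; bottleneck effects are modeled
  only through the explicit component switch.
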