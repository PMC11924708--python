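# Methods

This note records the statistical model behind `samgsd`, the defaults and
why they were chosen, the numerical machinery, and what the simulation
study does and does not demonstrate.

## Historical model and MAP prior

Aggregated historical control arms are pooled with the standard
binomial/logit-normal hierarchy:

    y_j ~ Binomial(n_j, theta_j)
    logit(theta_j) = mu + tau * z_j,   z_j ~ N(0, 1)
    mu ~ N(0, sd_mu^2)   (default sd_mu = 2)
    tau ~ Half-Normal(sd_tau)   (default sd_tau = 1)

The MAP prior is the posterior predictive of `expit(mu + tau * z_new)` for
a new exchangeable trial. The weak `N(0, 4)` prior on the logit-scale mean
spans event rates from well below 1% to above 99%; Half-Normal(1) on `tau`
admits substantial heterogeneity (odds-ratio variation of e^2 across
trials) without forcing it.

Sampling uses an affine-invariant ensemble MCMC sampler. Four fully
independent ensembles (16 walkers, 2,000 adaptation + 2,500 retained
sweeps, thinned by 8) are treated as chains for split-R-hat; a fit whose
worst R-hat reaches 1.01 raises rather than silently returning a dubious
prior. For the built-in four-study example this takes under a minute and
yields R-hat < 1.005. The test suite validates the sampler against a
brute-force grid posterior over `(mu, tau)` with Gauss-Hermite integration
of the study random effects.

A caution from the worked example: the predictive mean of this model on
the four historical studies is about 0.14, while the design carries a
historical point estimate of 0.179 taken from the published mixture
approximation. A proper hierarchical fit can never produce a predictive
mean above the largest observed study proportion (here 10/60 = 0.167), so
the published mixture is treated as a *fixture* — the design-time input —
rather than as a target the fitting pipeline is expected to recover.
Heterogeneity for these four studies is I^2 ≈ 0.91 on either the logit
(default, 0.5 continuity correction for zero cells) or raw-proportion
scale.

## EM beta-mixture approximation

The MCMC draws are compressed to a `K`-component beta mixture by EM
(default K = 2, AIC selection available). Component fits in the M-step are
weighted maximum-likelihood via the beta sufficient statistics
`E[log x], E[log(1-x)]`; initialisation is method-of-moments on a
rank-ordered split of the draws, making the fit deterministic given the
draws. The log-likelihood is asserted non-decreasing every iteration. A
component whose weight collapses below 1e-4 triggers a refit with one
component fewer; in practice EM keeps overlapping components at
non-trivial weight, so this path is defensive.

Mixture quantiles invert the exact mixture CDF (regularised incomplete
beta functions, bisection to 1e-8). For the published two-component
mixture this gives mean 0.179 and 95% equal-tailed interval
(0.077, 0.344); the interval's published upper endpoint (0.33) is not
reproducible from the published mixture parameters under any standard
convention (the 0.975 point is 0.344; the 95% HDI is (0.063, 0.319)), and
the package reports what it computes.

## SAM weight and weak component

The congruence weight uses the plug-in likelihood ratio: numerator at
`theta_h_hat`, denominator the larger of the likelihoods at
`theta_h_hat ± delta`, all in log space; `w = R/(1+R)`. With no control
data the weight is 1/2. `theta_h_hat` is fixed at design time (the MAP-EM
mixture mean); the weight is recomputed from *cumulative* control data at
each interim.

The weak component is `Beta(1, 1)` (uniform) by default. A mean-matched
`Beta(theta*c, (1-theta)*c)` variant is available but is **not** the
default because for low event rates its alpha parameter falls below 1,
where the ELIR integral diverges (see below) and no meaningful ESS — and
hence no enrolment adjustment — exists.

## ELIR effective sample size

For a beta mixture the local prior information
`-d^2 log p/d theta^2` is evaluated analytically from component densities
and integrated against the prior by adaptive quadrature (relative
tolerance 1e-6), divided by the binomial unit information
`1/(theta(1-theta))`. Two subtleties:

- For `Beta(a, b)` the integral equals `a + b` only when both parameters
  exceed 1. At `a = 1` exactly the corresponding term vanishes — the
  uniform prior has zero local information and ELIR ESS 0, although the
  limit from above is 2. ELIR is likewise not bracketed by component
  closed forms for mixtures: a 95:5 blend of Beta(1,1) and Beta(2,2) has
  ESS ≈ 0.10, not something in [2, 4]. The Monte-Carlo oracle in the test
  suite confirms both.
- When any component parameter is ≤ 1 the integrand can diverge at the
  boundaries; integration is then trimmed to `[1e-6, 1 - 1e-6]` and the
  trimmed prior mass is reported in `integration_error`.

A Poisson-style unit information (`1/theta`) is available behind a flag
for sensitivity analysis only; it does not reproduce the `a + b` property
and is not used anywhere by default.

## Group-sequential scaffold

One-stage sample size uses the unpooled normal-approximation formula
`n_per_arm = (z_{1-alpha} + z_{1-beta})^2 * 2 theta(1-theta) / M^2`,
rounded up per arm. The default convention rounds the control rate to two
decimals first (0.179 → 0.18, total 2,282 for the worked example); the
exact-rate variant is a config switch.

Boundaries: cumulative Hwang-Shih-DeCani spending
`level * (1 - e^{-gamma t}) / (1 - e^{-gamma})` for the one-sided type-I
error (efficacy, default gamma -4) and type-II error (futility, default
gamma -2, solved under the design alternative). Crossing probabilities
use the canonical recursion on the score scale (independent increments),
with 281-node Gauss-Legendre grids per continuation interval truncated at
±8 SD, bound solving by Brent's method to 1e-12. The design alternative's
drift is inflated until the futility and efficacy bounds meet at the
final look with total type-II error beta; the sample-size inflation is
`(drift/drift_fixed)^2` and `n_max` rounds up to the next even integer so
1:1 allocation stays possible.

Futility bounds are **binding** by default: the efficacy bounds are
solved with the futility bounds enforced (fixed-point iteration between
the two recursions). This choice was calibrated against the worked
example, which a non-binding accounting does not reproduce (it gives a
final bound of 1.68 and ceiling 2,452 instead of 1.64 and 2,386);
non-binding remains available. The boundary engine is validated against
brute-force simulation of the correlated statistic sequence in the test
suite, both under the null (total alpha) and at the design alternative
(total beta).

Bayesian thresholds are `Phi(Z_i)` applied to the *exact* solved bounds
(0.3381, 0.7384, … rather than the 2-decimal prints); interim comparisons
are strict, with threshold ties falling into the continuation region.

## Posterior inference

Beta mixtures are conjugate: components shift by the data, weights
reweight by beta-binomial marginal likelihoods in log space. The test-arm
prior is uniform (no borrowing applies to the test device). The posterior
probability of noninferiority integrates the test-arm posterior CDF
against the control-arm posterior density by adaptive quadrature
(absolute tolerance 1e-6); a Monte-Carlo oracle on random posterior pairs
guards its accuracy. Deterministic quadrature (rather than posterior
sampling) keeps a single trial simulation at ~30 ms.

## Trial engine

Stage 1 enrols the planned first-look total 1:1 under weak priors on both
arms — the SAM prior is first assembled only after the first interim, when
current control data exist to judge congruence. At each continuation the
engine recomputes `w` (or uses the frozen 0.5 for the static-borrowing
comparator), rebuilds the SAM prior, computes its ELIR ESS, and enrols the
next stage's planned increment *minus the rounded ESS*, never dropping
below the planned per-arm test enrolment; each patient is assigned to
control with probability `r/(1+r)`, `r = max(n_plan - ESS, 0)/n_plan`.
There is no top-up at the final analysis: the realised maximum enrolment
is below the design ceiling by roughly twice the ESS, matching how the
borrowing is meant to replace control patients. Posteriors always absorb
cumulative data; the SAM prior on the control arm is re-applied to the
full cumulative control counts at every analysis.

Per-trial randomness comes from a counter-based substream keyed by
`(seed, crc32(scenario id), trial index)`, so results are bitwise
reproducible and any scenario can be rerun in isolation.

## Scenario grid and what the simulations show

The default grid fixes the historical estimate and offsets the true
current control rate by `{0, -delta, -1.5 delta, -2 delta}`, crossing each
with the null (`theta_t = theta_c + M`) and the alternative
(`theta_t = theta_c`). At 1,000 simulations per scenario the adaptive
design holds the null rejection rate near 0.05 across all offsets, keeps
power near 0.8, and the mean first-interim weight decays from ~0.45
(congruent) to ~0.24 (two margins off). The default test suite runs 200
simulations per scenario with tolerances widened to ±3 binomial standard
errors at that size; the full 1,000-per-scenario grid is a longer run
(`samgsd replicate-example --n-sims 1000`, roughly 5–10 minutes per
design version on one CPU).

The generator draws exchangeable binomial outcomes at fixed true rates.
It does not emulate enrolment drift over calendar time, covariate
imbalance between historical and current populations, or misreported
historical counts — so passing operating characteristics here demonstrate
control under rate-level (in)congruence only, not robustness to
population-level confounding, which aggregate borrowing cannot address in
principle.

## Known limitations

- Binary endpoints only; the mixture-conjugacy machinery is
  beta-binomial specific.
- Aggregate historical data only (no individual-patient matching).
- The static-borrowing comparator reports a constant prior ESS by
  construction; published comparisons that show variable ESS under static
  weights are measuring a data-dependent quantity this package
  deliberately does not reproduce.
- The hierarchical sampler is ensemble MCMC, adequate for the low
  dimension here (2 + J parameters) but not tuned for dozens of
  historical studies.
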