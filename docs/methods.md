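# Methods

This note documents the models, the sampler, the comparison semantics, the
synthetic-data generators and the numerical choices behind `psybayes`.

## Models

All models share one pattern: a likelihood for the raw experimental
observations, optional hierarchical pooling across subjects, and posterior
draws obtained by MCMC. "Group-level mean draws" are the comparison
currency — the vector of per-draw values that represents what a scientist
would call the group's mean.

### Student-t location-scale model (`fit_ttest`)

Observations `y_i ~ StudentT(nu, mu, sigma)` with degrees of freedom
`nu > 0`, location `mu` and scale `sigma > 0`.  The heavy tails make `mu`
robust to outliers; for large `nu` the model collapses to a normal.  Groups
are fitted independently and compared afterwards through their `mu` draws.
`sigma` is a scale (standard-deviation-like) parameter.  Default priors:
flat on `mu` and flat on `log sigma` and `log nu` (scale-invariant).  `nu`
is not bounded below at 1; `mu` is reported as the location parameter
regardless, so the comparison semantics are unaffected.  On normal data
`nu` drifts to very large values — that is the normal limit, not a failure.

### Hierarchical exGaussian reaction-time model (`fit_reaction_time`)

A subject's reaction times are exponentially modified normal: the sum of a
`Normal(mu_i, sigma_i)` component and an exponential tail with *rate*
`lambda_i`, so the subject's expected reaction time is `mu_i + 1/lambda_i`
(all in seconds).  Subject parameters are pooled through group-level
normals `N(mu_mu, sigma_mu)`, `N(mu_sigma, sigma_sigma)` and
`N(mu_lambda, sigma_lambda)`; the latter two are truncated to positive
support, with the truncation constant included, because an untruncated
normal would put mass on negative scales and rates.  The group-level
expected reaction time is `E = mu_mu + 1/mu_lambda`.

`lambda` is parameterized as the exponential *rate* precisely so that this
group mean formula holds.  Group hyper-parameters get flat priors on their
support: flat on the real line for `mu_mu`, flat on `(0, inf)` for the
scales *and* for the positive locations `mu_sigma` and `mu_lambda`.  The
positive parameters are deliberately **not** given the scale-invariant
`1/x` default: the likelihood does not vanish as `mu_sigma -> 0`, so a
`1/x` prior would pile unbounded mass at zero and the chain would collapse
there.

Only correct-response trials should be modeled; the filter is a data-layer
option (`correct_only=` / `--filter-correct`), not part of the likelihood.
Subjects must be indexed contiguously from 1 to n (validated, with a
re-indexing hint in the error).

### Hierarchical Bernoulli-Beta success-rate model (`fit_success_rate`)

Subject `i` succeeds with probability `p_i`; the subject rates are pooled
through the mean-parameterized Beta prior `Beta(p*tau, (1-p)*tau)`, where
`p` is the group success rate and `tau` the concentration.  Defaults:
`p ~ Beta(1, 1)` and `tau` flat on `(0, 500]`.  The upper bound on `tau` is
required for propriety: the joint density of `(p_i, p, tau)` grows without
limit when the subject rates collapse onto the group rate while `tau`
grows, so an unbounded flat prior has no proper posterior.  `tau = 500`
corresponds to a between-subject standard deviation around 0.02 at
`p = 0.5` — effectively complete pooling, which is as far as psychological
data can usefully distinguish.  Subject rates are sampled on the logit
scale and reported as probabilities.

### Hierarchical linear model (`fit_linear`)

`y = alpha_i + beta_i * x + Normal(0, sigma_i)` per subject, with
group-level normals on intercepts, slopes and (positive-truncated)
residual scales.  `x` is used as given — no internal centering — so the
intercept keeps its interpretation at the start of the sequence;
`center_x=True` subtracts the grand mean of `x`.  The selectable mean
draws are `mu_alpha` ("intercept"), `mu_beta` ("slope") and `mu_sigma`
("sigma").  Group priors follow the same flat-on-support rule as the
reaction-time model.

### Six-component color model (`fit_color`)

Colors live in RGB (`[0, 255]` per channel) or HSV (hue in degrees,
saturation/value in `[0, 1]`).  Whichever space the data arrive in, the
other is derived per row (matplotlib's hexcone conversion; achromatic
input maps to hue 0), and six independent fits are run: truncated normals
for R, G, B on `[0, 255]` and S, V on `[0, 1]` — truncation constants
included — and a von Mises (circular normal) distribution for hue.  Hue is
radians internally, degrees at the interface.  Priors: flat on the
truncated-normal means, flat on positive support for the standard
deviations and the von Mises concentration `kappa`.  Identical input rows
raise a degenerate-variance error rather than silently fitting a
zero-width component.

### Bayesian bootstrap (`bayesian_bootstrap`)

Each replicate draws observation weights `w ~ Dirichlet(1, ..., 1_n)` and
evaluates the statistic under those weights, simulating the posterior of
the statistic rather than a sampling distribution.  A resampling mode
(redraw n rows with probabilities `w`, statistic unweighted) is also
provided; it layers multinomial noise on top of the Dirichlet weights, so
its draw distribution has the same center but a modestly wider spread than
the weighted mode — the two agree approximately, not exactly.  The default
is the weighted mode.  For the weighted mean of data `x`, the draws have
mean `mean(x)` and variance `sum((x - mean(x))^2) / (n(n+1))` exactly.

## Sampler

Models are declared as parameter blocks with support constraints; sampling
runs on the unconstrained scale (log transform for positive parameters,
scaled logit for interval parameters, free angle wrapped at read-out for
circular ones) with Jacobian corrections.  The kernel combines

1. componentwise Gaussian random-walk Metropolis with per-coordinate
   proposal scales adapted during warmup (Robbins-Monro towards 0.44
   acceptance), and
2. full-dimensional Metropolis moves whose proposal covariance is the
   empirical covariance of the warmup history (recomputed every 100
   sweeps, scalar step adapted towards 0.23 acceptance).

The global moves matter: hierarchical posteriors contain correlated ridges
(subject `mu_i` against `1/lambda_i`, group location against group scale)
that coordinatewise updates cross only by diffusion.  All chains advance
as one vectorized batch, so a fit is bit-reproducible from its seed and
settings.  Defaults are 4 chains, 1000 warmup and 1000 kept iterations per
chain; warmup draws are discarded before any diagnostic or summary.
Initialization is data-scaled (per-model moment estimates) with chain
jitter, retried up to 100 times until the log density is finite.
Correctness is contractual, not algorithmic: conjugate cases
(Beta-Bernoulli, normal mean) must match their analytic posteriors within
Monte Carlo error, and the test suite enforces exactly that.

### Priors

Five families are supported: uniform(lo, hi), normal(mean, sd),
gamma(shape, rate), beta(alpha, beta) and flat.  Two distinct "flat"
defaults exist and the distinction is deliberate:

* a parameter with **no prior attached** is flat on the *sampling*
  (unconstrained) scale — e.g. flat on `log sigma`, the scale-invariant
  choice used by the t-test model;
* an explicit **flat prior** is flat on the *constrained* support
  (Jacobian included) — used for hierarchical scales and positive group
  locations, where the `1/x` alternative is improper at zero.

## Comparison semantics

Comparisons are **draw-aligned**: the i-th draw of one group is compared
with the i-th draw of the other, so `P(a > b) = #{a_i > b_i}/n`.  (An
all-pairs cross product is *not* used; with five draws per group of
123,128,121,137,110 versus 118,126,119,110,122 the aligned rule gives
4/5 = 0.8, the cross product would give 17/25.)  Exact ties without a ROPE
split evenly between the two sides, so degenerate comparisons are
deterministic.  With a ROPE `[lo, hi]`, draws whose difference falls
inside the interval count as "practically equal" and the strict
inequalities are evaluated on the rest; the three probabilities sum to 1
by construction.  Every pair also reports the 95% HDI of the differences.
Multi-group comparisons add, per group, the probability of having the
largest (smallest) draw per index, ties split evenly among the tied
groups.

Hue comparisons wrap differences to `(-pi, pi]` and interpret the ROPE on
the wrapped scale (degrees at the interface, converted internally).

Each probability carries a Monte Carlo standard error computed by chunking
the aligned draws into 20 contiguous segments and taking the standard
deviation of the per-segment probabilities over `sqrt(20)`.  This is a
pragmatic estimator — it under-weights autocorrelation at lags longer than
a segment — and is reported as guidance, not as a calibrated interval.

`compare_distributions` applies the same semantics to posterior
*predictive* draws: for each posterior draw, `n_per_draw` new observations
are simulated from the likelihood at those parameter values.  For the
reaction-time model the predictive simulates the group-typical subject
(`mu_mu`, `mu_sigma`, `mu_lambda`); integrating over the subject
distribution would describe a new *subject*, not a new *observation*, and
the group-typical reading matches the group-mean formula `E = mu_mu +
1/mu_lambda`.

## Diagnostics

* **HDI**: the shortest contiguous interval over the sorted draws
  containing `ceil(mass*n)` of them; ties broken towards the smallest
  lower bound.  This equals the exhaustive shortest-window scan by
  construction (property-tested).  Nesting of HDIs across masses holds for
  unimodal draw sets; for strongly multimodal draws the shortest window
  can jump between modes, so no nesting guarantee is made there.  A
  circular variant scans arcs on the wrapped circle for hue draws.
* **Split R-hat**: each chain is halved, `Rhat = sqrt(var_plus / W)` with
  `var_plus = ((n-1)W + B)/n` over the half-chains.  The classic
  (non-rank-normalized) form; it equals 1 at convergence and is invariant
  under affine transformation of the draws.
* **Effective sample size**: multi-chain autocorrelations
  `rho_t = 1 - (W - mean-autocovariance_t)/var_plus`, truncated by Geyer's
  initial-positive-sequence rule (stop at the first non-positive paired
  sum), `n_eff = N / (1 + 2*sum rho_t)` capped at the total draw count —
  no super-efficiency is reported, so an antithetic chain reports exactly
  `N`.  This is one defensible estimator among several; rank-normalized
  variants are out of scope.
* **se_mean** is `sd / sqrt(n_eff)` for every summary row, by definition.

Summaries are computed on post-warmup draws only and serialize as CSV with
columns `parameter, mean, se_mean, sd, 2.5%, 97.5%, n_eff, Rhat`.

## Synthetic data generators

The generators emulate the *structure* of four classic experiments so the
full workflows run end-to-end with known ground truth; they are synthetic
stand-ins, not the original datasets, and their defaults are chosen to
reproduce the qualitative findings of those experiment types.

* **Flanker** (`generate_flanker`): 22 subjects per group, 80 trials each.
  Control group exGaussian parameters `mu_mu = 0.40 s`, `sigma_mu = 0.04`,
  `mu_sigma = 0.06`, `sigma_sigma = 0.01`, `mu_lambda = 10` (a 100 ms mean
  exponential tail), `sigma_lambda = 1.5` — typical flanker reaction times
  of ~0.5 s with realistic between-subject spread.  The test group's
  `mu_mu` is shifted by `group_shift` (default 0.05 s, a robust clinical
  slowing).  Correctness is Bernoulli with subject rates drawn from
  `Beta(p*tau, (1-p)*tau)`, `p = 0.95`, `tau = 60`, and the test group's
  `p` lowered by `error_rate_gap` (default 0.01 — accuracy differences in
  this paradigm are small).  `raw_ids=True` emits subject ids starting at
  22 to exercise the re-indexing validation.
* **Adaptation level** (`generate_adaptation`): two groups of 10 subjects,
  10 assessments on a continuous 9-point response scale; group intercepts
  (8.0, 5.8) and slopes (-0.11, +0.12) — the light-first group starts high
  and drifts down, the heavy-first group the reverse, converging over
  trials; between-subject sds 0.5 / 0.02, trial noise sd 0.5.
* **Stroop** (`generate_stroop`): 40 subjects, one completion time per
  condition in the paired layout; condition means (43, 46, 55, 69) s
  ordered reading-neutral < reading-incongruent < naming-neutral <
  naming-incongruent, subject speed effect sd 5 s, trial noise sd 3 s.
* **Afterimages** (`generate_afterimages`): 50 responses per stimulus for
  six stimuli (red, green, blue, cyan, magenta, yellow); response hue
  ~ von Mises(stimulus hue + offset, kappa = 30), saturation/value
  ~ clipped normals near 1 (sd 0.08); responses returned as integer RGB
  with the HSV ground truth recorded.  `hue_offset = pi` produces
  complementary-hue responses.

What the generators do **not** emulate: sequential effects and learning
within a session, contaminant trials (lapses, anticipations) in reaction
times, item-level structure, missing data, and perceptual nonuniformity of
color space.  Passing recovery tests therefore demonstrates that the
models recover the parameters of their own data-generating processes at
realistic sizes — not that those processes capture every feature of real
experiments.

## Problem sizes used in the shipped checks

The repeated-recovery checks (20 seeded replications per model) run at
reduced sizes chosen as the smallest configurations at which the posterior
is still data-dominated: 8 subjects x 30 trials for the reaction-time
model, 10 x 30 for success rates, 8 subjects for the linear model, 40
color responses, n = 200 for the t-test, with 2-chain samplers of 300-600
warmup/kept iterations.  The end-to-end flanker check runs at the
generator defaults (22 subjects x 80 trials per group).  Coverage is asserted at >= 16/20, the binomial
tolerance for a nominal 95% interval at 20 replications.

## Known limitations

* The random-walk kernel needs dense data per subject; with very few
  trials per subject and many subjects, mixing of the group scales slows
  down and `n_eff` should be checked before interpreting results.
* Flat hyper-priors on group scales are improper; with fewer than ~3
  subjects the hierarchical posteriors may be improper or extremely
  diffuse, and the single-subject linear model relies on the subject-level
  parameters only.
* The exGaussian likelihood models correct-response times only; error
  trials must be filtered out upstream.
* Comparison SEs (the segment estimator) are indicative, not calibrated.
* Color components are fitted independently; correlations between hue and
  saturation (common in real responses) are not modeled.
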