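# Methods

This note documents the statistical machinery in `embermap`: the models,
their assumptions, the defaults and why, what the synthetic generator does
and does not emulate, and the numerical choices that matter.

## Data model

The universal input is a stratified counts table: one row per
(area, year, sex, 5-year age band, method group) holding a death count and
the person-years at risk.  Method groups are `charcoal` (the emerging
method) and `non_charcoal` (all established methods).  Areas are opaque
string ids; every join in the package is by id, never by file order.
Adjacency ("areas sharing a border") travels as a GAL neighbour file;
weights w_ij are binary contiguity, optionally row-standardised.  An
ordinal urbanisation level 1 (most urban) … 7 (most rural) accompanies each
area; levels 1–3 are classed urban, 4–7 rural.

## Direct standardisation

Rates are directly standardised against a standard population's band
weights w_s (Segi 1960 world standard by default, WHO 2000 as an
alternative; the Segi standard is the "world standard population" of the
era the pipeline targets).  For analyses restricted to ages 15+, the
weights of the retained bands are renormalised to sum to one.  The variance
uses the usual Poisson approximation, var = 10¹⁰ Σ w_s² d_s/n_s², which
underlies the normal CIs on rate differences.  Method-share proportions
use Wilson score intervals, which behave sensibly in sparse cells (0 of n
and k of k give exact 0 / 1 bounds); the choice of interval is a package
convention.  Moving averages over calendar years are centred; endpoints
use a shrinking window and are flagged `partial` so plots can span the full
series without fabricating data.

## SMRs

Expected deaths come from indirect standardisation: national sex- and
age-specific rates, pooled over the analysis period from the input counts
themselves, multiplied by each area's person-years in the same strata.
Because the reference is internal, Σᵢ Eᵢ = Σᵢ Oᵢ (closure) and the
E-weighted mean SMR is exactly 1.  Sexes are analysed separately with
sex-specific references.  Areas with E = 0 (no population in the covered
strata) are dropped from spatial models and rendered as no-data on maps.

## Hierarchical Poisson smoothing

Raw SMRs are unstable where E is small, so the package fits

    O_i ~ Poisson(E_i θ_i),    log θ_i = α + u_i + v_i

with three variants: **global** (v only: exchangeable Normal(0, 1/τ_v)
heterogeneity, shrinking every area toward the national mean in proportion
to its uncertainty), **local** (u only: intrinsic CAR, u_i | u_{−i} ~
Normal(mean of neighbours, 1/(τ_u n_i)), shrinking toward the neighbour
mean), and **convolution** (both).  Priors are the WinBUGS-era vague
convention: improper flat on α and Gamma(0.5, 0.0005) on both precisions
(configurable).  The ICAR prior is improper; identifiability is restored by
re-centring u to mean zero after every sweep, with α absorbing the level.
Isolated areas keep u_i = 0 (with a warning): an island has no neighbour
mean to borrow.

**Sampler.**  A custom MCMC scheme: conjugate Gibbs for τ_u
(shape a + (n_active − n_components)/2, rate b + uᵀLu/2, L the graph
Laplacian) and τ_v; adaptive random-walk Metropolis for α and for each
u_i, v_i.  The v updates are fully vectorised (their full conditionals are
mutually independent); the u updates are vectorised over greedy graph
colour classes — no two areas in a class are adjacent, so updating a class
simultaneously is an exact composition of independent single-site kernels.
Step sizes adapt toward 44% acceptance in windows of 50 iterations during
burn-in only, then freeze, preserving detailed balance for the retained
draws.  Four parallel chains by default, seeded from independent streams
spawned from one master seed; a fit is reproducible bit-for-bit given the
seed and iteration schedule.

**Diagnostics.**  Convergence is summarised by the Brooks–Gelman potential
scale reduction factor on α, the precisions and five randomly chosen θ_i
(reported, not enforced; the `converged_` flag uses R-hat < 1.05).  The
precisions mix slowly at short schedules — a known property of convolution
models, where u and v compete for the same variability — so production
runs should use the CLI defaults (20,000 iterations, 10,000 burn-in)
rather than the short schedules the test suite uses for speed.  Model
comparison uses DIC with deviance D(θ) = −2 Σ [O_i log μ_i − μ_i −
log O_i!], pD = D̄ − D(θ̄); pD can be negative on pathological fits and is
reported as-is.

**Variance partition.**  The share of area variability attributed to the
local component is, per draw, ψ = var(u)/(var(u) + var(v)) using empirical
marginal variances of the effect vectors (posterior median and 95% CrI
reported).  A `conditional` alternative based on 1/τ_u and 1/τ_v is also
implemented; the marginal definition is the default because the conditional
CAR variance parameter is not on the same scale as the marginal spatial
variability and tends to overstate the local share.

## Moran's I

I = (n/S0) Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)², row-standardised weights by
default.  Because raw small-area rates have population-dependent sampling
noise, the default analysis variable is the Assunção–Reis empirical-Bayes
standardised rate z_i = (p_i − b)/√(a + b/n_i), where b is the overall
rate, a the method-of-moments between-area variance (clamped at 0), and
n_i the area's population (person-years, or E on the SMR scale).  Inference
is a one-sided (greater) permutation test with p = (1 + #{I_perm ≥ I_obs})
/(n_perm + 1); 999 permutations by default; ties count toward the numerator
(conservative).  Permutations are uniform relabelings of the values over
areas, batched as a single quadratic form for speed.

## Map classification

Smoothed SMRs are classed into five categories symmetric on the log scale
around a middle class [0.9, 1.1] (closed at both ends, shown white); one
log-step of r = 1.1/0.9 per side puts the outer breaks at 0.9²/1.1 ≈ 0.736
and 1.1²/0.9 ≈ 1.344, so c1·c4 = c2·c3 = 0.99.  The outer step size is a
declared package convention (only the symmetry and the middle class are
intrinsic to the scheme) and is configurable.  Colours are a 5-class
divergent blue–white–red scheme emitted as name + hex tokens; the GeoJSON/
CSV classification is the source of truth and plotting is a thin consumer.

## Synthetic scenario generator

The generator exists so every downstream stage is testable without a
mortality registry.  It emulates:

- **Geography**: a rook-contiguity grid; urbanisation as a smooth spatial
  score (proximity to a random urban core plus smoothed noise) quantised
  to 7 levels with fixed area shares (level 5 deliberately tiny), so levels
  cluster spatially; log-normal populations, larger in urban levels, tuned
  so levels 1–3 hold ≈73% of the population with ≈35% of the areas.
- **Risk surface**: u from a proper CAR (precision ∝ Laplacian + 1e-6
  ridge, drawn per connected component, centred, rescaled to an exact
  empirical SD σ_u — default 0.3) plus iid noise v (σ_v = 0.1).  Generation
  needs a proper distribution; inference still uses the intrinsic CAR.
- **Epidemic**: the new method's age-standardised rate is 0 before an
  onset year (default 1999) and then follows an urbanisation-level-specific
  logistic curve — plateaus calibrated so that the final-period (2005–07)
  male rates run from ≈11 per 100,000 in the most urban level to ≈7 in the
  most rural, with urban midpoints a year earlier; female rates are scaled
  by 0.37.  The area relative risk exp(u+v) multiplies the new-method rate.
- **Background**: established-method rates are constant over calendar time
  (male 25, female 12 per 100,000 age-standardised), with a ×1.3
  multiplicative excess in rural levels 4–7.
- **Counts**: deaths ~ Poisson(person-years × rate), with fixed adult age
  composition and rising-with-age background risk vs working-age-peaked
  new-method risk.  Rates are parameterised on the age-standardised scale
  (profiles are renormalised against the standard weights), so realised
  standardised rates estimate the configured values directly.

One master seed is split into independent streams (lattice, surface,
counts), so adding strata does not perturb earlier draws, and runs are
bit-identical under a fixed seed.

**What it does not emulate** — and therefore what passing tests do not
establish about real registries: real geography and adjacency (islands,
coastlines), migration, age-period-cohort structure beyond the logistic ×
age-profile rate model, method misclassification and under-ascertainment
of suicide, and secular change in background rates.  The generator's ages
are 15+ by default (the analysis population), configurable, since
published rate tables do not always state their age floor.

## Problem sizes

The test-suite and acceptance-script simulations are sized for a single
CPU: parameter recovery uses 300 areas at 4 chains × 5,000 iterations;
replicate-based directional checks (DIC preference, ψ dominance) use a
10×10 lattice at 2 chains × 1,500 iterations per fit; scenario-level
contrasts (urban gradient, rural–urban collapse) run at 19×19 = 361 areas
— the scale of a national township registry — because the between-period
rate contrast needs that population for adequate power.

## Known limitations

- The ICAR implementation targets contiguity graphs; general weighted CAR
  is out of scope, as are proper-CAR inference, space×time interaction
  models and INLA-style approximations.
- Short MCMC schedules give honest but high R-hat on the precisions; DIC
  and θ summaries are much less sensitive to this than τ themselves.
- The Moran test permutes values over areas, which assumes exchangeability
  under the null; the EB adjustment mitigates, but does not remove,
  heteroscedasticity from very unequal populations.
- pD (and hence DIC) uses the posterior mean of θ as the plug-in, the
  classic choice; alternatives (median, mean of log θ) are not exposed.
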