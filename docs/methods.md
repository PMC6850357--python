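# Methods

This note records the statistical model the package implements, the
numerical choices behind it, what the simulator does and does not emulate,
and the design decisions taken where more than one construction was
defensible.

## Model

### Sighting process

Latent sighting counts of marked individual `s` at occasion `t` are
Poisson log-normal: `x_{s,t} ~ Poisson(exp(α_t + σ_t z))` with a standard
normal individual effect `z`. Two heterogeneity structures are supported:

- **within** — a fresh effect `z_{s,t}` per individual-occasion
  (independent over time);
- **across** — a single effect `z_s` per individual, shared across
  occasions (correlated sighting rates).

A detected mark is individually identified with probability `r_t`;
identified counts are `y_{s,t}` and the per-occasion total of
unidentified marked sightings is `e_t`. Marginally over the effect, a
count has mean `λ̄_t = exp(α_t + σ_t²/2)` and variance
`η_t = λ̄_t + exp(2α_t)(exp(2σ_t²) − exp(σ_t²))`. The simulator's
`(λ, τ)` parameterisation sets `α, σ` so that the marginal mean is `λ` and
the marginal variance `λ(1+τ)`.

### Demography and zero inflation

Marked animals occupy one of three states per occasion: 1 dead or
permanent emigrant, 2 alive off the study area, 3 alive on the study
area. A newly released cohort enters with distribution
`[1−w_t, w_t(1−g_t), w_t g_t]`; between occasions survivors move between
the on/off-area states with Markovian temporary-emigration probabilities
(`γ″` on→off, `γ′` off→off) and survive with probability `φ_t`. States 1
and 2 emit only zero counts; state 3 emits the Poisson log-normal count.
Released-but-never-sighted animals therefore contribute through a
mixture over all three states — the zero inflation that distinguishes
this estimator from the zero-truncated comparator.

### Composite likelihood

Dependencies between the marked histories `Y`, unidentified totals `e`,
and unmarked totals `u` induced by shared individual effects are ignored;
the three components are multiplied as if independent:

1. **Marked histories.** Within model: an HMM product with marginal
   state-3 emissions `p_{s,t} = ∫ Poisson(y_{s,t}; e^{α_t+σ_t z} r_t) φ(z) dz`.
   Across model: the conditional HMM product is evaluated at each
   quadrature node and mixed, because the shared effect couples occasions.
2. **Unidentified totals.** `e_t ~ TN_(0,∞)(n_t λ̄_t (1−r_t), n_t κ_t)`
   with `κ_t = λ̄_t(1−r_t) + exp(2α_t)(1−r_t)²(exp(2σ_t²)−exp(σ_t²))`.
   When `r_t = 1` the component is dropped (and `e_t > 0` is an error).
3. **Unmarked totals.** `u_t ~ TN_(0,∞)(U_t λ̄_t, U_t η_t)`.

Where `n_t` is unknown it is replaced by the Horvitz–Thompson estimate
`n̂_t = Σ_{s∈M_t} I(y_{s,t}>0) / p_t`, `p_t = 1 − E_z exp(−e^{α_t+σ_t z} r_t)`.
`n̂_t` is recomputed from the current parameters at every likelihood
evaluation but treated as a plug-in constant in differentiation — it is a
replacement value, not a parameter. For the across model `p_t` uses the
marginal formula; the covariance this ignores in `u` is ignored by
construction of the composite likelihood.

Counts in the truncated-normal components are treated as continuous, with
no continuity correction; `u_t = 0` is evaluated at 0 (finite density).

### Identifiability

With fully time-dependent `w` and `g`, only the terminal product
`w_T·g_T` is identified (the likelihood is exactly flat along the ridge
`(c·w_T, g_T/c)`); with `T = 1` the same holds for `w_1·g_1`.
`validate_model_spec` warns in both cases, and a test asserts the
flatness. In the zero-truncated comparator, `γ′` for the first interval
carries no information.

## Quadrature

Physicists' Gauss–Hermite quadrature (weight `exp(−v²)`) with the
transformation `λ*_l = exp(α + √2 σ v_l)` and normalisation `1/√π`.
`L = 101` points everywhere by default (configurable per model
specification); at `L = 101` the log-normal mean identity is reproduced
to better than 1e−8 for σ ≤ 1.5, and σ = 0 collapses to a single exact
node for any `L`.

## Estimation

- Link functions: identity for `α`, log for `σ` and `U`, logit for all
  probabilities. Constraint designs per parameter family: time-constant,
  fully time-dependent, fixed values, per-occasion pins (e.g.
  `w₁ = g₁ = 1` when `n₁` is known), explicit link-scale design matrices,
  and equality ties (e.g. random emigration `γ″ = γ′`).
- Optimiser: L-BFGS-B on the link scale, relative log-likelihood
  tolerance 1e−8. `fit()` defaults to three deterministic, data-driven
  starts (a moment-matched sighting rate with probabilities at 0.8 and
  σ = 0.2, plus two opposite-direction perturbations). The study runner
  uses a single start: on probe datasets the single start reached the
  multi-start optimum to within 0.01 log-likelihood units, and replicated
  experiments dominate total runtime.
- Variances: central finite-difference Hessian on the link scale, step
  `1e−4·(1+|θ|)`, inverted to a covariance matrix (pseudo-inverse with a
  warning flag if not positive definite). Plain observed-information
  variances are used deliberately — no composite-likelihood sandwich
  correction — to match how these models are used in practice.
- Derived abundance: `N_t = U_t + n_t` (known) or `U_t + n̂_t`; SEs by
  the delta method with finite-difference gradients through the whole
  derived expression; 95% intervals are log-normal around `N_t` (the
  standard convention for abundance, keeping bounds positive).
- AICc uses `−2logL + 2K + 2K(K+1)/(ess−K−1)` with effective sample size
  defaulting to the number of marks ever released, `M_T` (configurable;
  no canonical choice exists for these models). Model averaging uses
  Akaike weights with unconditional variance
  `Σ_m w_m (var_m + (θ̂_m − θ̄)²)`.

### Model-specification YAML

The CLI reads model specifications from YAML:

```yaml
estimator: ziPNE        # or ztPNE
heterogeneity: within   # none | within | across
L: 101                  # Gauss-Hermite points
designs:                # per parameter family; unlisted -> constant
  alpha: constant       # one shared link-scale coefficient
  sigma: {fixed: 0.0}   # pinned natural values (scalar or per-occasion list)
  U: time               # fully time-dependent
  w: {design: constant, fixed: {1: 1.0}}   # pin occasion 1, constant elsewhere
  gammaPP: {tie: gammaP}                   # equality constraint
  # alpha: {matrix: [[1,0],[1,1],[1,2]]}   # explicit link-scale design matrix
```

Links: identity (`alpha`), log (`sigma`, `U`), logit (probabilities).

## Simulator

Generates from the exact model: an initial marked cohort
`R₁ ~ Poisson(E(R₁))` alive on-area (so `n₁ = M₁` is known and
`w₁ = g₁ = 1`), an unmarked pool `~ Poisson(E(U₁))`, shared three-state
demography for marked and unmarked animals, Poisson log-normal counts
with per-individual (across) or per-individual-occasion (within) effects,
binomial `r`-thinning of marked counts into identified/unidentified
(distributionally identical to independent Poisson splits), and marking
of each unmarked on-area animal with probability 0.02 between occasions.
No unmarked recruits after occasion 1, so abundance declines through
mortality and permanent emigration. Scenario defaults are the shared
study conditions (`T = 7`, `φ = 0.95`, `γ″ = γ′ = 0.1`, `w = 0.95`,
`g = 0.9`).

Newly marked animals' entry states are drawn from the
`[1−w, w(1−g), wg]` distribution — the same law the fitted likelihood
assumes — and the animal leaves the unmarked pool; a simulator flag
(`entry_states="realized"`) instead carries the animal's realised
demographic state forward, for sensitivity analyses. The w-vector reading
is the default because fitted models estimate `w, g < 1` for those
cohorts.

What the simulator does **not** emulate: density dependence, covariate
effects, unequal sampling effort, misidentification, and recruitment into
the unmarked population. Passing tests therefore show correct recovery of
the generating model under its own assumptions, not robustness to the
violations real field data exhibit.

## Replicated experiments and problem sizes

The study runner aggregates percent relative bias of `N_t` (averaged over
occasions, then replicates), absolute bias for the demographic
probabilities, exact-binomial coverage of 95% intervals, RMSE, and
failure counts (non-converged fits are excluded from metrics but
reported). Exports follow the nested-loop ordering: heterogeneity block,
then λ (decreasing), τ (increasing), r, E(R₁), E(U₁) — best case first,
worst case last.

The packaged end-to-end checks run scaled-down versions of the factorial
experiments: 100 replicates for the moderate within-model recovery check,
60 paired replicates for the zero-inflated vs zero-truncated comparison,
50–100 replicates for the worst-case across-model coverage. Replicate `k`
of a scenario uses seed `master + k`, so aggregates are independent of
execution order.

## Numerical details and edge cases

- Poisson masses via log-gamma; probabilities are floored at 1e−300
  inside logarithms; truncated-normal variances floored at 1e−12.
- `p_t` below 1e−10 raises rather than dividing (a Horvitz–Thompson
  estimate with numerically zero detection is meaningless).
- A likelihood evaluation that overflows or leaves the parameter space
  returns a large penalty to the optimiser instead of propagating NaNs.
- Boundary diagnostics flag fitted probabilities within 1e−4 of 0/1 and
  σ̂ > 3.

## Zero-truncated comparator

The comparator keeps only sighted individuals, enters each at its first
sighted occasion in the on-area state with a zero-truncated entry
emission (`p_{s,b′}/p_{b′}`, applied node-wise under across
heterogeneity), and shares the unidentified/unmarked components with the
zero-inflated estimator. This isolates the consequences of zero
truncation itself; it is not a re-implementation of any particular
historical software's likelihood (which differs, e.g., in using an ad-hoc
adjustment for unidentified marks rather than an `r` parameter), and is
used only for qualitative comparisons.

## Known limitations

- Simultaneous within + across heterogeneity is not supported.
- No profile-likelihood intervals; interval coverage inherits the
  delta-method/log-normal approximations.
- The composite likelihood ignores `Y`–`e`–`u` covariances by design;
  under extreme across-heterogeneity with poor identification the
  resulting intervals undercover. In the `τ = 5`, `r = 0.5` scenario
  class at the small sample sizes, `σ` is underestimated (mean `σ̂ ≈ 1.0`
  against a generating 1.21 in the worst cell), `N_t` is overestimated
  by roughly 8–13%, and measured 95%-interval coverage averages about
  0.79–0.82 over the class (cell values from ≈0.71 to ≈0.94) — plain
  observed-information variances carry no composite-likelihood sandwich
  correction.
- The truncated-normal approximations for `e_t` and `u_t` are moment
  approximations, least accurate when `n_t λ̄_t` is very small.
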