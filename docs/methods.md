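# Methods

## Model and design

`ctdose` implements a three-parameter Bayesian dose-finding design for
phase I trials with continuous toxicity responses. The response at dose
`x ∈ (x_min, x_max)` is modelled as `y ~ Normal(β (x − x_min)^ν, σ²)`; the
mean is zero at `x_min`, which presumes responses have been transformed and
centred so that the expected response at the minimum dose vanishes (the
case-study module shows such a transform; the package does not auto-centre
arbitrary inputs). The design rests on the usual monotone dose–toxicity
assumptions for cytotoxic (or monotone-biomarker) agents: negligible effect
below `x_min`, mild at `x_min`, increasingly severe across the range,
life-threatening at `x_max`, and intolerable above it. These are encoded as
config validation (doses outside `[x_min, x_max)` are rejected) rather than
as testable model structure.

A dose-limiting toxicity is `y ≥ η`; the maximum tolerated dose `ξ` is the
largest dose whose DLT probability is at most `θ = 1 − γ`. With
`0 < σ < η/Φ⁻¹(γ)` and `β` above the lower bound
`l(σ, ν) = (η − σΦ⁻¹(γ))/(x_max − x_min)^ν`, the MTD is
`ξ = x_min + ((η − σΦ⁻¹(γ))/β)^{1/ν}` and lies inside the dose range; the
identity `Pr[Y(ξ) < η] = γ` is exact and is verified to 1e-9 in the tests.

Priors: `β | ν, σ ~ U(l(σ,ν), u(σ,ν))` with
`u(σ,ν) = η/(x_max − x_min)^ν + σΦ⁻¹(γ)` (the upper bound only makes the
conditional uniform proper; the support claim needs only `l`);
`σ ~ C⁺(0,1)` truncated to `(0, η/Φ⁻¹(γ))`; `ν ~ logNormal(0, δ²)` with unit
median. `log_prior` includes all normalising constants (the tests integrate
it to 1 by cubature) and returns `-inf` off-support instead of raising, so
samplers reject gracefully.

### Parameters that matter

| parameter | units | default | role |
|---|---|---|---|
| `eta` | response units | — | DLT threshold on the continuous response |
| `gamma` | probability (0.5, 1) | 0.99 for novel agents, 0.6–0.9 otherwise | homogeneity constant; `1 − gamma` is the target toxicity level |
| `alpha` | probability (0, 1) | 0.001–0.1 | feasibility bound; the next dose is the posterior `alpha`-quantile of the MTD, so smaller values escalate more cautiously |
| `delta` | — | 0.1 (0.5 when real non-linearity is expected) | prior scale of `ν`; larger values allow stronger curvature |
| `x_min, x_max` | dose units | — | admissible range; the MTD is assumed (and under the prior, forced) to lie inside |
| `cohort_size` | patients | 1 | 1 = fully sequential; 3 is the common cohort design |

## Posterior computation

The posterior is sampled by slice-within-Gibbs, with the state
parameterised as `(b, ν, σ)` where `b = (β − l)/(u − l) ∈ (0, 1)`. Because
the conditional prior of `β` is uniform on `(l, u)`, `b` is exactly
uniform(0,1) a priori and independent of `(ν, σ)`; updating `ν` or `σ` with
`b` held fixed carries the slope along with its moving support. This matters:
the raw `(β, ν)` posterior is a narrow curved ridge (the support `(l, u)`
shifts by orders of magnitude as `ν` varies), and coordinate updates in `β`
itself mix poorly there. Each coordinate uses a univariate slice update
(Neal 2003): interval shrinkage on the bounded supports of `b` and `σ`,
stepping-out plus shrinkage for `log ν`, where the prior is Gaussian.
Conditionals for `b` and `σ` reuse sufficient statistics so only the `ν`
update touches the data; the kernel is numba-compiled because each dose
decision requires a fresh chain and replicated studies need thousands.

Defaults: 4000 iterations, 1000 burn-in, no thinning — three parameters, a
cheap likelihood, and small `n` make this ample. Initialisation is always
in-support: `σ` at half its upper bound, `ν = 1`, `β` at the support
midpoint. Chains are bit-reproducible given the seed. One observation is
allowed; the posterior is then strongly prior-driven by construction.
Correctness is validated against an independent dense 3-D grid-integration
oracle (means and quantiles agree within Monte-Carlo error on small
datasets; the oracle grids `σ` on the log scale because one or two
exactly-fittable observations concentrate the likelihood near `σ = 0`).

The dose rule takes the empirical `α`-quantile of the MTD draws with the
inverted-CDF (type-1) convention, which never exceeds the interpolated
quantile — the conservative choice for overdose control.

## Trial engine and option composition

Fully sequential and cohort-sequential loops share one engine with a
pluggable response source (truth-driven simulator, recorded data, or an
interactive generator that yields doses and awaits live responses). The
response stream and the MCMC chains use separate seeded streams, so
changing sampler settings never perturbs the simulated patients. A trial
that trips the stopping rule (count of responses at or above a severity cut
exceeding a threshold) reports metrics on the accrued patients, with the
last assigned dose as the MTD estimate.

Rule options compose in a fixed order — increment cap, then monotone
escalation, then grid snapping — so both the cap and monotonicity act on
the continuous scale before discretisation. Equidistant grid ties resolve
to the lower dose (safety first). When monotone escalation and a grid are
both active, snapping is restricted to grid doses at or above the current
dose, and the rule errors if none exists. Two snapping conventions are
provided: `nearest` (the default) and `ceiling`, which escalates to the
next grid level as soon as the quantile clears the current dose — the
conventional "one level per cohort" practice; the bundled enzyme-depletion
case study uses `ceiling`, which reproduces its recorded escalation
decisions, whereas nearest snapping provably cannot (several recorded
escalations occur while the quantile is still below the midpoint between
levels).

## Diagnostics

Four metrics summarise a trial against a known truth: `NPD(n)` (responses
at or above `η`), `NPO(n)` (doses above the true MTD), `BTM(n) = x_n − ξ₀`,
and `RMSE(n) = |x_n − ξ₀|/ξ₀` (the square root of the single-trial relative
squared error; reported under the conventional name RMSE). NPD and NPO
measure safety, BTM and RMSE accuracy; a rule with positive replicated BTM
escalates past the truth and is unsafe. The long-run DLT fraction of the
design is bounded by `1 − γ`, which the tests check on a 500-patient
simulated trial with two Monte-Carlo standard errors of slack.

`replicate_experiment` repeats independent trials from spawned child seeds
and reports medians (midpoint convention for even counts) plus quartiles
and per-replicate records. Because medians from a reduced number of
replicates are noisy, comparisons against reference medians use a
percentile-bootstrap interval of the median.

## What the synthetic generator does and does not emulate

Simulated patients draw `y ~ Normal(β₀(x − x_min)^{ν₀}, σ₀²)` with the true
slope pinned by the true MTD (`β₀ = (η − σ₀Φ⁻¹(γ))/(ξ₀ − x_min)^{ν₀}`), i.e.
the generator matches the model family exactly and is homoscedastic.
Passing tests therefore demonstrate self-consistency (correct posterior,
correct rule, correct engine) and the design's operating characteristics
*under the model*; they do not probe misspecification of the curve shape or
of constant variance. The case-study resampler is the one deliberately
misspecified source: it resamples recorded enzyme activities per dose with
dose-specific uniform perturbations (half-widths 8/6/4/2 fmol/mg at
40/60/80/100 mg/m²), so its variance shrinks with dose while the model
pools a single `σ`.

## Problem sizes and numerical choices

Replicated experiments in the tests and the acceptance script use 100
replicates per design cell and 20–25 replicates for the case-study
re-designs — enough to pin the medians and modes being checked while
keeping a full run to a few minutes; the long-trial DLT check uses
2000-iteration chains. Identity checks use tolerance 1e-9; the power-curve
fit multi-starts the optimiser at `ν ∈ {0.25, 0.5, 1, 2}` to escape the
shallow valley typical of power fits; out-of-support densities are `-inf`;
`Φ⁻¹` comes from scipy's standard-normal quantile.

## Known limitations

- Alternative mean curves (Richards, Gompertz), group-specific slopes, and
  per-patient repeated measures are out of scope.
- The case-study dose grid includes 120 mg/m², where no patients were ever
  treated; if a re-design reaches it, responses are borrowed from the
  100 mg/m² pool (tightest perturbation bound) with a warning.
- Replicated re-designs of the case study show that with a well-mixed
  posterior the standard (`α = 0.05`) variant most often ends at
  100 mg/m², one level above the single recorded standard run (80 mg/m²);
  that run's early decisions sat within Monte-Carlo noise of the
  escalation boundaries, so its endpoint is not the modal one under
  replication.
- At very small sample sizes the replicated median bias is mildly more
  conservative (more negative) than the reference medians; the gap shrinks
  with sample size (about −1.8 vs −1.46 at 18 patients, −0.92 vs −0.85 at
  45). Noisier quantile estimates in a dose-finding loop systematically
  accelerate escalation (upward noise triggers escalations that then
  self-correct), so designs evaluated with a lower-variance quantile
  estimate look slightly more conservative.
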