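# Methods

## Problem and model

`milbridge` estimates the parameters θ of a one-dimensional Itô diffusion

    dX_t = μ(X_t, θ) dt + σ(X_t, θ) dB_t

from low-frequency observations X_{τ_0}, …, X_{τ_M}.  Between observations
the transition density is intractable in general, so the sampler augments the
data with imputed path points on a finer grid (m subintervals per
observation pair) and runs a Metropolis-within-Gibbs chain on
(θ, X^imp | X^obs).  The package's focus is the comparison of two one-step
approximations of the transition density — Euler–Maruyama and Milstein — used
both for likelihood evaluation and for proposing imputed points.

The working example is geometric Brownian motion (GBM),
dX = αX dt + σX dB with θ = (α, σ²), whose exact lognormal transition law
provides (i) the synthetic-data generator and (ii) an exact-likelihood
benchmark posterior, so that every approximation error can be measured.  A
CIR model (dX = β(κ−X) dt + σ√X dB) is registered with the same interface.

## Transition kernels

*Euler*: Gaussian with mean y + μ(y)Δt and variance σ²(y)Δt.

*Milstein*: the scheme map y′ = y + μΔt + σΔB + ½σσ′(ΔB²−Δt) is quadratic in
ΔB, so the one-step law is a two-branch transformed Gaussian with closed-form
density

    π(y′|y) = exp(−C/D) / sqrt(2πΔt·A) · [exp(−√A/D) + exp(√A/D)],
    A = σ² + 2σσ′(y′ − y − (μ − σσ′/2)Δt),  C = (σ² + A)/(2σ),  D = σσ′²Δt.

Its support is bounded by the extremum of the quadratic map,
g* = y − σ/(2σ′) + (μ − σσ′/2)Δt — a lower bound when σσ′ > 0 (e.g. GBM,
where g* = y(½ + (α − σ²/2)Δt)), an upper bound when σσ′ < 0.  The density
diverges at the bound (an integrable inverse-square-root singularity) and is
zero beyond it.  When σ′ = 0 everything reduces exactly to Euler.

Numerical choices: all density work is done in log space; the
two-exponential bracket is evaluated as √A/D + log1p(exp(−2√A/D)) since √A/D
can exceed 10³; A is clipped to zero within 1e-12·σ² of the bound to avoid
roundoff NaNs.  The closed form was verified against the analytic two-root
change-of-variables density, by quadrature normalization, and by a
Kolmogorov–Smirnov comparison with the scheme sampler.

## Path proposals

Imputed points are proposed one at a time, left to right, within a segment
pinned at both ends.  Families:

* **left-conditioned** (lc-euler / lc-milstein): one-step kernel from the
  left neighbour; ignores the right anchor, so acceptance is poor — kept for
  completeness.
* **modified bridge, Euler (MBE)**: Gaussian with mean on the chord to the
  anchor and variance (Δ₊/(Δ₊+Δt))·σ²(left)·Δt, i.e. with the left point's
  drift and diffusion substituted for the proposed point's (Durham–Gallant).
* **modified bridge, Milstein (MBM)**: the product
  π^Mil(x | left, Δt) · π^Mil(anchor | x, Δ₊) with the second factor's
  coefficients evaluated at x (no substitution).  Its support is the
  intersection of the first factor's lower bound with the second factor's
  constraint; for the GBM the latter is an upper bound anchor/c when
  c = ½ + (α−σ²/2)Δ₊ > 0, a vacuous (negative) lower bound when c < 0, and
  absent when c = 0.  The feasible set can be empty, in which case the point
  falls back to the MBE proposal (with the Euler factor in the acceptance
  ratio); fallbacks are counted and did not occur in the study conditions.
* **diffusion-bridge Milstein (DBM)**: the closed-form Milstein kernel with
  the bridge-SDE coefficients μ → (anchor−left)/t_rem and
  σ → sqrt(Δ₊/t_rem)·σ(left) (the square root makes the Euler limit of its
  variance agree with the MBE variance).  Direct sampling, no normalization.

MBM has no closed-form normalization constant.  Normalization (needed
whenever a segment contains more than one imputed point, because the left
conditioning values differ between numerator and denominator) follows a
fixed numerical protocol: a 512-point log-spaced grid over the feasible set
(infinite upper bounds truncated where the density falls below 1e-30 of the
running maximum), a bounded scalar refinement of the grid maximum, restriction
to the sub-interval with density ≥ 1e-20 of the maximum, rescaling by the
maximum, then adaptive quadrature.  Sampling uses rejection from the
rectangle I × (0, d_max) with d_max the located maximum inflated by 5% as a
guard.  The boundary singularities are numerically invisible at these
settings (their mass is far below 1e-20 of the total); the rejection sampler
therefore effectively targets the density truncated at d_max, a documented
approximation.  With a single imputed point the constants cancel and the
acceptance ratio is formed without normalization — making the unit acceptance
of the matched-scheme modified bridge hold *exactly* in floating point.

Gaussian-family proposals can leave the state space (negative GBM values);
such points are re-drawn and counted, and the proposal density is not
renormalized for the truncation — matching the procedure under which the
reference results are defined.  In the study conditions re-draws stay far
below 1‰ of iterations.

## The sampler

Each iteration performs

1. **parameter update** — a joint random walk: Gaussian steps (variance 0.25)
   for real-line components, lognormal steps (log-variance 0.25) for positive
   ones, with the Jacobian ∏ θ*_j/θ_j in the acceptance ratio; all components
   accepted or rejected together against the product of one-step densities
   along the augmented path times the prior (α ~ N(0, 10),
   σ² ~ InvGamma(2, 2), prior mean 2 — mean/variance parameterizations);
2. **path update** (m ≥ 2) — blocks of λ = 5 subintervals; observed points
   inside a block split it into independent sub-bridges whose interior points
   are proposed sequentially; the block is accepted or rejected collectively.

By default an iteration sweeps one full partition of the path into
non-overlapping λ-blocks at a uniformly random offset, so each iteration
refreshes every imputed point once.  This makes fixed-iteration budgets
comparable across methods (an alternative `path_update="single"` mode updates
one uniformly placed block per iteration).  A zero-likelihood initial state
(possible for the Milstein likelihood with linearly interpolated imputed
points, whose support bound can exclude observed increments) is always left
in favour of any proposal until a positive-density state is reached.

Method names follow the study: EULER-m1 / MIL-m1 (no imputation), MBE-E,
MBE-M, MBM-M, DBM-M (proposal scheme – likelihood scheme), plus EXACT-m1
(closed-form GBM likelihood), which doubles as the benchmark sampler.

## Benchmark and diagnostics

The "true posterior" reference is a Metropolis–Hastings chain with the exact
lognormal GBM likelihood — the likelihood is available in closed form, so a
long chain (default 200k retained draws) plays the role of an
effectively-exact posterior sample.  It is validated against a 2-d grid
quadrature of the posterior.  Summaries are per-component mean / median /
variance after a 5000-iteration burn-in.  Effective sample size is the
multivariate determinant criterion ESS = n (det Λ / det Σ)^{1/p} with Λ the
sample covariance and Σ the multivariate batch-means estimator at batch size
⌊√n⌋ — the standard consistent choice; absolute ESS values depend on this
tuning and are treated as indicative.  Accuracy is the RMSE, across replicate
paths, of a posterior summary minus the benchmark's.

## Simulation study and problem sizes

The study conditions are fixed by `StudySpec` defaults: 100 exact GBM paths
on [0, 1] with θ = (1, 2), x₀ = 100, M = 20 observations (Δt = 0.05),
m ∈ {1, 2, 5}, 25 000 iterations per chain (5000 burn-in), λ = 5.  Fixed
iteration counts replace wall-clock budgets so results are hardware
independent (`milbridge fit --wall-clock` restores a time-budget mode).
The desk profile runs 20 paths.  Chains for the GBM run through a compiled
(numba) twin of the generic engine, tested for pointwise density agreement
and distributional chain agreement; MBM-M at m > 2 uses the generic engine.

At these budgets the bias of a scheme/proposal combination is resolved
whenever it exceeds the per-chain Monte Carlo error of a posterior-mean
estimate.  For the strongly mixing m = 1 samplers that error is ≈ 0.01–0.02
and the σ² accuracy ordering (Milstein < Euler bias) reproduces clearly.
For data-augmented runs at m = 5 the coupling between σ² and the imputed
path inflates the σ² autocorrelation time to order 10², so posterior-mean
RMSEs below ≈ 0.05 cannot be resolved with 20 000 retained iterations — they
require chain lengths of order 10⁵–10⁶ (as used for the reference values).
The acceptance-rate and exact-unit-acceptance results are budget independent.

## What the generator does and does not emulate

The generator draws from the exact GBM law — the same process the methods
assume — with complete, error-free, equidistant observations.  Passing tests
therefore demonstrate correctness of the samplers and the relative accuracy
of the approximation schemes under ideal conditions; they say nothing about
measurement error, partial observation, irregular sampling, or model
misspecification, none of which are modelled here.

## Known limitations

* The closed-form Milstein machinery is restricted to scalar diffusions (or
  multi-dimensional ones satisfying the commutativity condition checked by
  `milstein_applicable`); no Lévy-area approximation is attempted.
* The MBM feasible set is implemented analytically for the GBM (and the
  trivial σ′ = 0 case); other state-dependent models would need their own
  case analysis.
* Non-renormalized re-draws of out-of-state-space Gaussian proposals are a
  small, counted approximation inherited from the reference procedure.
* The CIR model is registered and usable with every kernel/proposal that does
  not require the GBM-specific feasible-set analysis, but no CIR study is
  shipped.
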