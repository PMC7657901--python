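# milbridge

Bayesian parameter inference for one-dimensional Itô diffusions
`dX_t = μ(X_t, θ) dt + σ(X_t, θ) dB_t` observed at low frequency, via
Markov chain Monte Carlo with data augmentation — and, at its core, the
**closed-form Milstein transition density** as a higher-order alternative to
the ubiquitous Euler–Maruyama approximation, both for likelihood evaluation
and for bridge-type proposals of the imputed path points.

The package is aimed at statisticians and modellers in the life sciences who
fit SDE models (growth, pharmacokinetics, interest-rate-style mean
reversion) to sparse time series and want to know whether a higher-order
scheme buys accuracy per iteration.

## The method in brief

With observations `X_{τ_0}, …, X_{τ_M}`, each inter-observation interval is
split into `m` subintervals and the missing points are treated as latent
variables.  A Metropolis-within-Gibbs sampler alternates

1. `θ | path` — joint random-walk update (Gaussian for α, lognormal for σ²,
   with the corresponding Jacobian), accepted against
   `∏_k π(X_{t_{k+1}} | X_{t_k}, θ) · p(θ)`;
2. `path | θ` — blockwise bridge proposals of the imputed points, accepted
   collectively per block.

The one-step density `π` is either the Euler Gaussian or the Milstein density

    π^Mil(y'|y) = exp(−C/D)/√(2πΔt·A) · [exp(−√A/D) + exp(√A/D)],

a two-branch transformed Gaussian supported on one side of the bound
`g* = y − σ/(2σ′) + (μ − σσ′/2)Δt` (for GBM: `g* = y(½ + (α−σ²/2)Δt)`).
Path proposals come in three flavours: modified bridge based on Euler (MBE),
modified bridge based on Milstein (MBM, normalized by quadrature and sampled
by rejection), and the diffusion-bridge Milstein (DBM) — the Milstein kernel
with the bridge drift `(anchor−left)/t_rem` and shrunk diffusion.  The method
grid of the shipped study is EULER/MIL at `m=1` and MBE-E, MBE-M, MBM-M,
DBM-M at `m ∈ {2, 5}`, with geometric Brownian motion as the benchmark model
because its exact lognormal law yields ground-truth posteriors.

See `docs/methods.md` for the complete model description, numerical choices
and limitations.

## Worked example

```python
import numpy as np
from milbridge import (StudySpec, generate_trajectories, run_gbm_chain_fast,
                       summarize, multivariate_ess)

spec = StudySpec(n_paths=1, master_seed=11)     # GBM: alpha=1, sigma2=2, x0=100
times, paths = generate_trajectories(spec)      # 20 observations, dt = 0.05
obs = paths[0]

res = run_gbm_chain_fast(times, obs, "dbm-m", m=2, n_iter=25_000, seed=1)
s = summarize(res.draws, burn_in=5000)
ess = multivariate_ess(res.draws[5000:])
print(f"alpha : mean={s.mean[0]:.3f} median={s.median[0]:.3f} var={s.variance[0]:.3f}")
print(f"sigma2: mean={s.mean[1]:.3f} median={s.median[1]:.3f} var={s.variance[1]:.3f}")
print(f"param acceptance = {res.param_accept_rate:.3f}, "
      f"path acceptance = {res.path_accept_rate:.3f}, multivariate ESS = {ess.ess:.0f}")
```

prints

```
alpha : mean=-0.142 median=-0.154 var=1.541
sigma2: mean=1.912 median=1.783 var=0.404
param acceptance = 0.403, path acceptance = 0.847, multivariate ESS = 769
```

On this particular path the exact-likelihood benchmark posterior
(`run_gbm_chain_fast(..., "exact-m1", m=1, n_iter=205_000)`) has mean
α = −0.017, σ² = 1.904: with only 20 observations the drift is weakly
identified (the prior `N(0, 10)` dominates), while the DBM-M posterior mean
of σ² lands within 0.01 of the exact one — the diffusion parameter is where
the Milstein scheme pays off.  The `path acceptance = 0.847` is the collective
block acceptance of the bridge proposals; for the matched-scheme modified
bridge (`"mbm-m"`, `m=2`) it is exactly 1 by construction.

The same runs are available from the shell:

```bash
milbridge simulate --out runs/sim --seed 1 --n-paths 100
milbridge fit runs/sim/path_000.csv --method dbm-m --m 2 --iters 25000 --out runs/fit
milbridge study --out runs/study --profile desk     # 20 paths, all methods
```

`study` writes `table1_rmse.csv` (accuracy of each method × m against the
exact posterior), `table2_efficiency.csv` (ESS, acceptance rates, event
counters) and per-parameter deviation density plots.

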