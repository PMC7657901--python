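"""Metropolis-within-Gibbs sampler for diffusion parameters with data
augmentation.

Each iteration alternates

* **parameter update** — a joint random-walk proposal on all parameter
  components (Gaussian steps for real-line components, lognormal steps for
  positive ones, with the corresponding Jacobian in the acceptance ratio),
  accepted against the product of one-step transition densities along the
  augmented path times the prior; and
* **path update** (only when ``m > 1``) — imputed points are refreshed in
  blocks of ``lambda_block`` subintervals.  Within a block, observed points
  split the interior into independent sub-bridges whose points are proposed
  sequentially by the configured bridge proposal; the block is accepted or
  rejected collectively.

By default one full sweep of non-overlapping blocks (at a uniformly random
offset) is performed per iteration, so that an iteration refreshes the whole
latent path once; ``path_update="single"`` instead updates a single uniformly
placed block per iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from . import bridge_proposals as bp
from .sde_models import DiffusionModel, gbm_model
from .transition_kernels import get_kernel

__all__ = [
    "PriorSpec",
    "RWProposalSpec",
    "ChainConfig",
    "ChainResult",
    "AugmentedPath",
    "METHODS",
    "initialize",
    "param_log_accept",
    "choose_update_interval",
    "path_update",
    "run_chain",
]

# method name -> (likelihood scheme, proposal kind or None for m = 1)
METHODS = {
    "euler-m1": ("euler", None),
    "mil-m1": ("milstein", None),
    "exact-m1": ("exact", None),
    "mbe-e": ("euler", "mbe"),
    "mbe-m": ("milstein", "mbe"),
    "mbm-m": ("milstein", "mbm"),
    "dbm-m": ("milstein", "dbm"),
    "lc-e": ("euler", "lc-euler"),
    "lc-m": ("milstein", "lc-milstein"),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent priors: ``alpha ~ N(mean, var)`` and
    ``sigma2 ~ InvGamma(shape, scale)`` (prior mean ``scale/(shape-1)``)."""

    alpha_mean: float = 0.0
    alpha_var: float = 10.0
    sigma2_shape: float = 2.0
    sigma2_scale: float = 2.0

    def log_density(self, theta) -> float:
        alpha, sigma2 = float(theta[0]), float(theta[1])
        if sigma2 <= 0:
            return -math.inf
        lp = stats.norm.logpdf(alpha, self.alpha_mean, math.sqrt(self.alpha_var))
        lp += stats.invgamma.logpdf(sigma2, self.sigma2_shape, scale=self.sigma2_scale)
        return float(lp)

    def sample(self, rng) -> np.ndarray:
        alpha = rng.normal(self.alpha_mean, math.sqrt(self.alpha_var))
        sigma2 = self.sigma2_scale / rng.gamma(self.sigma2_shape, 1.0)
        return np.array([alpha, sigma2])

    def sigma2_prior_mean(self) -> float:
        return float(stats.invgamma.mean(self.sigma2_shape, scale=self.sigma2_scale))


@dataclass(frozen=True)
class RWProposalSpec:
    """Per-component random-walk variances; positive components take
    lognormal steps ``theta* ~ LN(log theta, gamma2)``, the others Gaussian
    steps ``theta* ~ N(theta, gamma2)``."""

    gamma2: tuple = (0.25, 0.25)

    def __post_init__(self):
        if any(g <= 0 for g in self.gamma2):
            raise ValueError("proposal variances must be positive")


@dataclass(frozen=True)
class ChainConfig:
    method: str
    m: int = 1
    n_iter: int = 10_000
    burn_in: int = 5000
    lambda_block: int = 5
    seed: Optional[int] = None
    path_update: str = "sweep"  # "sweep" | "single"

    def __post_init__(self):
        key = self.method.lower()
        if key not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; available: {sorted(METHODS)}")
        scheme, proposal = METHODS[key]
        if (proposal is None) != (self.m == 1):
            raise ValueError(f"method {self.method!r} requires m {'== 1' if proposal is None else '>= 2'}")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def scheme(self) -> str:
        return METHODS[self.method.lower()][0]

    @property
    def proposal(self) -> Optional[str]:
        return METHODS[self.method.lower()][1]


@dataclass
class AugmentedPath:
    """Augmented path: strictly increasing times, values, and a mask that is
    True at observed points (which the path update never changes)."""

    times: np.ndarray
    values: np.ndarray
    observed: np.ndarray

    @classmethod
    def from_observations(cls, obs_times, obs_values, m: int) -> "AugmentedPath":
        obs_times = np.asarray(obs_times, dtype=float)
        obs_values = np.asarray(obs_values, dtype=float)
        if obs_times.ndim != 1 or obs_times.shape != obs_values.shape or len(obs_times) < 2:
            raise ValueError("need matching 1-d time/value arrays with at least two observations")
        if np.any(np.diff(obs_times) <= 0):
            raise ValueError("observation times must be strictly increasing")
        M = len(obs_times) - 1
        n = M * m
        times = np.empty(n + 1)
        observed = np.zeros(n + 1, dtype=bool)
        for i in range(M):
            times[i * m : (i + 1) * m] = np.linspace(obs_times[i], obs_times[i + 1], m, endpoint=False)
            observed[i * m] = True
        times[-1] = obs_times[-1]
        observed[-1] = True
        values = np.interp(times, obs_times, obs_values)
        values[observed] = obs_values
        return cls(times=times, values=values, observed=observed)

    @property
    def n_intervals(self) -> int:
        return len(self.times) - 1


def initialize(obs_times, obs_values, config: ChainConfig, priors: PriorSpec, rng,
               model: Optional[DiffusionModel] = None):
    """Draw initial parameters from the prior and linearly interpolate the
    imputed points."""
    model = model or gbm_model()
    obs_values = np.asarray(obs_values, dtype=float)
    if math.isfinite(model.state_lower) and np.any(obs_values <= model.state_lower):
        raise ValueError("observations must lie inside the state space")
    theta = priors.sample(rng)
    path = AugmentedPath.from_observations(obs_times, obs_values, config.m)
    return theta, path


def _log_likelihood(path: AugmentedPath, theta, kernel, model) -> float:
    dts = np.diff(path.times)
    lp = kernel.log_density(path.values[1:], path.values[:-1], dts, theta, model)
    return float(np.sum(lp))


def propose_params(theta, rw: RWProposalSpec, model: DiffusionModel, rng) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    out = theta.copy()
    for j, positive in enumerate(model.positive_params):
        step = math.sqrt(rw.gamma2[j]) * rng.standard_normal()
        out[j] = math.exp(math.log(theta[j]) + step) if positive else theta[j] + step
    return out


def param_log_accept(theta_new, theta_old, path: AugmentedPath, scheme: str,
                     priors: PriorSpec, rw: RWProposalSpec,
                     model: Optional[DiffusionModel] = None) -> float:
    """Log acceptance probability of the joint random-walk parameter move:
    likelihood ratio x prior ratio x lognormal-step Jacobian.  An invalid
    current state (zero likelihood) is always left in favour of a valid
    proposal."""
    model = model or gbm_model()
    kernel = get_kernel(scheme, model)
    lp_new = _log_likelihood(path, theta_new, kernel, model) + priors.log_density(theta_new)
    lp_old = _log_likelihood(path, theta_old, kernel, model) + priors.log_density(theta_old)
    if lp_old == -math.inf:
        return 0.0
    jac = 0.0
    for j, positive in enumerate(model.positive_params):
        if positive:
            jac += math.log(theta_new[j] / theta_old[j])
    return min(0.0, lp_new - lp_old + jac)


def choose_update_interval(path: AugmentedPath, lambda_block: int, rng):
    """Uniformly placed block of ``min(lambda, n)`` subintervals; the block
    endpoints stay fixed during the update."""
    n = path.n_intervals
    if n < 1:
        raise ValueError("path must have at least two points")
    L = min(lambda_block, n)
    a = int(rng.integers(0, n - L + 1))
    return a, a + L


def _sweep_blocks(n: int, lam: int, rng):
    """Non-overlapping blocks of length ``lam`` at a uniformly random offset,
    covering all subintervals."""
    r = int(rng.integers(0, lam)) if lam < n else 0
    bounds = [0]
    b = r if r > 0 else lam
    while b < n:
        bounds.append(b)
        b += lam
    bounds.append(n)
    return list(zip(bounds[:-1], bounds[1:]))


def _subbridges(path: AugmentedPath, b0: int, b1: int):
    """Split the block (b0, b1) at interior observed points; return the index
    ranges of sub-bridges that contain at least one imputed interior point."""
    anchors = [b0] + [k for k in range(b0 + 1, b1) if path.observed[k]] + [b1]
    return [(i0, i1) for i0, i1 in zip(anchors[:-1], anchors[1:]) if i1 - i0 >= 2]


def _update_block(path: AugmentedPath, theta, b0: int, b1: int, scheme: str,
                  proposal: str, model, rng, counters) -> Optional[bool]:
    """Propose and collectively accept/reject one block.  Returns None when
    the block contains no imputed point."""
    segs = _subbridges(path, b0, b1)
    if not segs:
        return None
    zcache: dict = {}
    log_ratio = 0.0
    invalid_old = False
    new_finite = True
    proposals = []
    for i0, i1 in segs:
        times = path.times[i0 : i1 + 1]
        v_old = path.values[i0 : i1 + 1]
        v_new, q_new = bp.propose_segment(times, v_old, theta, model, proposal,
                                          rng, counters=counters, zcache=zcache)
        t_new = bp.segment_log_target(times, v_new, theta, model, scheme)
        t_old = bp.segment_log_target(times, v_old, theta, model, scheme)
        q_old = bp.segment_log_q(times, v_old, theta, model, proposal,
                                 counters=counters, zcache=zcache)
        if t_old == -math.inf or q_old == -math.inf:
            invalid_old = True
        if t_new == -math.inf:
            new_finite = False
        log_ratio += (t_new - q_new) - (t_old - q_old)
        proposals.append((i0, i1, v_new))
    if invalid_old:
        accept = new_finite
    else:
        u = 1.0 - float(rng.random())  # in (0, 1]
        accept = math.log(u) <= log_ratio
    if accept:
        for i0, i1, v_new in proposals:
            path.values[i0 + 1 : i1] = v_new[1:-1]
    return accept


def path_update(path: AugmentedPath, theta, config: ChainConfig, rng,
                model: Optional[DiffusionModel] = None, counters: Optional[dict] = None):
    """One path-update step.  Returns ``(n_proposed_blocks, n_accepted_blocks)``."""
    model = model or gbm_model()
    counters = counters if counters is not None else {}
    scheme, proposal = config.scheme, config.proposal
    if proposal is None:
        return 0, 0
    n = path.n_intervals
    if config.path_update == "single":
        blocks = [choose_update_interval(path, config.lambda_block, rng)]
    else:
        blocks = _sweep_blocks(n, config.lambda_block, rng)
    proposed = accepted = 0
    for b0, b1 in blocks:
        try:
            res = _update_block(path, theta, b0, b1, scheme, proposal, model, rng, counters)
        except bp.NumericalFailureError:
            counters["numerical_failures"] = counters.get("numerical_failures", 0) + 1
            continue
        if res is None:
            continue
        proposed += 1
        accepted += int(res)
    return proposed, accepted


@dataclass
class ChainResult:
    """Parameter draws and bookkeeping of one MCMC run."""

    draws: np.ndarray
    param_accept_rate: float
    path_accept_rate: Optional[float]
    counters: dict
    seed: Optional[int]
    config: ChainConfig
    final_path: Optional[AugmentedPath] = None

    @property
    def post_burn_in(self) -> np.ndarray:
        return self.draws[self.config.burn_in :]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.draws, columns=["alpha", "sigma2"]).rename_axis("iter")


def run_chain(obs_times, obs_values, config: ChainConfig,
              priors: Optional[PriorSpec] = None,
              rw: Optional[RWProposalSpec] = None,
              model: Optional[DiffusionModel] = None,
              rng=None, theta0=None) -> ChainResult:
    """Run the Metropolis-within-Gibbs sampler on one observed path."""
    model = model or gbm_model()
    priors = priors or PriorSpec()
    rw = rw or RWProposalSpec()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    theta, path = initialize(obs_times, obs_values, config, priors, rng, model)
    if theta0 is not None:
        theta = np.asarray(theta0, dtype=float).copy()
    counters: dict = {}
    draws = np.empty((config.n_iter, len(theta)))
    n_acc_param = 0
    n_prop_path = n_acc_path = 0
    for it in range(config.n_iter):
        theta_star = propose_params(theta, rw, model, rng)
        log_zeta = param_log_accept(theta_star, theta, path, config.scheme, priors, rw, model)
        u = 1.0 - float(rng.random())
        if math.log(u) <= log_zeta:
            theta = theta_star
            n_acc_param += 1
        if config.m > 1:
            p, a = path_update(path, theta, config, rng, model, counters)
            n_prop_path += p
            n_acc_path += a
        draws[it] = theta
    return ChainResult(
        draws=draws,
        param_accept_rate=n_acc_param / config.n_iter,
        path_accept_rate=(n_acc_path / n_prop_path) if n_prop_path else None,
        counters={
            "negative_redraws": counters.get("negative_redraws", 0),
            "euler_fallbacks": counters.get("euler_fallbacks", 0),
            "numerical_failures": counters.get("numerical_failures", 0),
        },
        seed=config.seed,
        config=config,
        final_path=path,
    )
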