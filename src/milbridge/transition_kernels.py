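"""One-step transition kernels under the Euler–Maruyama and Milstein schemes.

The Euler scheme

    Y_{k+1} = Y_k + mu dt + sigma dB

is a linear map of the Gaussian increment, so its transition density is
Gaussian with mean ``y + mu dt`` and variance ``sigma^2 dt``.  The Milstein
scheme adds the term ``0.5 sigma sigma' (dB^2 - dt)`` and is therefore a
*quadratic* map of ``dB``.  Its one-step density has the closed form

    pi(y' | y) = exp(-C/D) / sqrt(2 pi dt A) * [exp(-sqrt(A)/D) + exp(sqrt(A)/D)]

with

    A = sigma^2 + 2 sigma sigma' (y' - y - (mu - sigma sigma'/2) dt),
    C = (sigma^2 + A) / (2 sigma),
    D = sigma sigma'^2 dt,

the two exponentials corresponding to the two Brownian-increment roots of the
quadratic.  The density is supported only where ``A >= 0``, i.e. on one side
of the extremum

    g* = y - sigma/(2 sigma') + (mu - sigma sigma'/2) dt

of the quadratic map: a lower bound when ``sigma sigma' > 0``, an upper bound
when ``sigma sigma' < 0``.  When ``sigma' = 0`` the scheme (density and
sampler) degenerates to the Euler scheme.

The ``*_coeffs`` functions work directly on scalar/array drift and diffusion
values; they are reused by the diffusion-bridge proposal, which evaluates the
same closed form with substituted coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .sde_models import DiffusionModel

__all__ = [
    "MilsteinDensityTerms",
    "DegenerateKernelError",
    "TransitionKernel",
    "get_kernel",
    "euler_step_sample",
    "milstein_step_sample",
    "euler_log_density",
    "milstein_log_density",
    "milstein_support_bound",
    "milstein_terms",
    "euler_log_density_coeffs",
    "milstein_log_density_coeffs",
    "milstein_step_coeffs",
    "milstein_support_bound_coeffs",
]

_LOG_2PI = math.log(2.0 * math.pi)

# relative clipping width for A at the support boundary, in units of sigma^2
_A_CLIP = 1e-12


class DegenerateKernelError(ValueError):
    """The one-step kernel has zero diffusion and no density."""


@dataclass(frozen=True)
class MilsteinDensityTerms:
    """The terms A, C, D of the closed-form Milstein density at one point,
    together with the support bound g* and its orientation."""

    A: float
    C: float
    D: float
    bound: float
    bound_kind: str  # "lower" | "upper" | "none"


# ---------------------------------------------------------------------------
# coefficient-level kernels (mu, sigma, sigma' given explicitly)
# ---------------------------------------------------------------------------

def euler_log_density_coeffs(y_next, y, dt, mu, sig):
    """Gaussian log-density with mean ``y + mu dt``, variance ``sig^2 dt``."""
    if np.any(np.asarray(sig) == 0):
        raise DegenerateKernelError("Euler kernel is degenerate: sigma(y) = 0")
    var = np.asarray(sig, dtype=float) ** 2 * np.asarray(dt, dtype=float)
    z = np.asarray(y_next, dtype=float) - np.asarray(y, dtype=float) - np.asarray(mu) * np.asarray(dt)
    out = -0.5 * (_LOG_2PI + np.log(var)) - 0.5 * z * z / var
    return out if np.ndim(out) else float(out)


def milstein_support_bound_coeffs(y, dt, mu, sig, sigp):
    """Extremum g* of the quadratic Milstein map and the bound kind."""
    s = np.asarray(sig, dtype=float) * np.asarray(sigp, dtype=float)
    if np.ndim(s) == 0:
        if s == 0:
            return -math.inf, "none"
        g = float(y) - float(sig) / (2.0 * float(sigp)) + (float(mu) - 0.5 * float(s)) * float(dt)
        return g, ("lower" if s > 0 else "upper")
    raise ValueError("support bound is a scalar-state operation")


def milstein_log_density_coeffs(y_next, y, dt, mu, sig, sigp):
    """Closed-form Milstein log-density; ``-inf`` outside the support.

    Vectorized over ``y_next`` (and broadcastable ``y``, ``dt``, ``mu``,
    ``sig``, ``sigp``).  Where ``sigma' = 0`` the Euler log-density is
    returned instead.
    """
    y_next = np.asarray(y_next, dtype=float)
    y = np.asarray(y, dtype=float)
    dt = np.asarray(dt, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sig = np.asarray(sig, dtype=float)
    sigp = np.asarray(sigp, dtype=float)

    s = sig * sigp
    if np.all(s == 0):
        return euler_log_density_coeffs(y_next, y, dt, mu, sig)

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        A = sig * sig + 2.0 * s * (y_next - y - (mu - 0.5 * s) * dt)
        # clip roundoff-negative A exactly at the bound
        A = np.where((A < 0) & (A > -_A_CLIP * sig * sig), 0.0, A)
        feasible = A >= 0
        A_safe = np.where(feasible, A, 1.0)
        sqrtA = np.sqrt(A_safe)
        C = (sig * sig + A_safe) / (2.0 * sig)
        D = sig * sigp * sigp * dt
        # stable evaluation of log{ exp(-C/D)/sqrt(2 pi dt A) * 2 cosh(sqrt(A)/D) }
        lp = (
            -0.5 * (_LOG_2PI + np.log(dt) + np.log(A_safe))
            - C / D
            + sqrtA / D
            + np.log1p(np.exp(-2.0 * sqrtA / D))
        )
        lp = np.where(feasible, lp, -np.inf)
        if np.any(s == 0):
            lp_euler = euler_log_density_coeffs(y_next, y, dt, mu, np.where(sig == 0, 1.0, sig))
            lp = np.where(s == 0, lp_euler, lp)
    return lp if lp.ndim else float(lp)


def milstein_step_coeffs(y, dt, mu, sig, sigp, db):
    """Milstein update ``y + mu dt + sig db + 0.5 sig sig' (db^2 - dt)``."""
    y = np.asarray(y, dtype=float)
    db = np.asarray(db, dtype=float)
    out = y + mu * dt + sig * db + 0.5 * sig * sigp * (db * db - dt)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# model-level kernels
# ---------------------------------------------------------------------------

def _coeffs(y, theta, model: DiffusionModel):
    return model.drift(y, theta), model.diffusion(y, theta), model.diffusion_dy(y, theta)


def euler_step_sample(y, dt, theta, model: DiffusionModel, db=None, rng=None, size=None):
    """One Euler step from ``y``; ``db`` may be supplied or drawn from rng."""
    if db is None:
        db = rng.normal(scale=math.sqrt(dt), size=size)
    mu, sig, _ = _coeffs(y, theta, model)
    out = np.asarray(y, dtype=float) + mu * dt + sig * np.asarray(db)
    return out if np.ndim(out) else float(out)


def milstein_step_sample(y, dt, theta, model: DiffusionModel, db=None, rng=None, size=None):
    """One Milstein step from ``y``; equals the Euler step when sigma' = 0."""
    if db is None:
        db = rng.normal(scale=math.sqrt(dt), size=size)
    mu, sig, sigp = _coeffs(y, theta, model)
    return milstein_step_coeffs(y, dt, mu, sig, sigp, db)


def euler_log_density(y_next, y, dt, theta, model: DiffusionModel):
    """Euler one-step log transition density; ``-inf`` if the conditioning
    point lies outside the state space."""
    if not np.all(model.in_state_space(y)):
        return _outside(y_next, y, model)
    mu, sig, _ = _coeffs(y, theta, model)
    return euler_log_density_coeffs(y_next, y, dt, mu, sig)


def milstein_log_density(y_next, y, dt, theta, model: DiffusionModel):
    """Milstein one-step log transition density; ``-inf`` outside the scheme
    support and ``-inf`` if the conditioning point is outside the state
    space."""
    if not np.all(model.in_state_space(y)):
        return _outside(y_next, y, model)
    mu, sig, sigp = _coeffs(y, theta, model)
    return milstein_log_density_coeffs(y_next, y, dt, mu, sig, sigp)


def _outside(y_next, y, model):
    ok = model.in_state_space(y)
    out = np.where(ok, np.nan, -np.inf) + np.zeros_like(np.asarray(y_next, dtype=float))
    return out if np.ndim(out) else float(out)


def milstein_support_bound(y, dt, theta, model: DiffusionModel):
    """Support bound (g*, kind) of the Milstein kernel started at ``y``."""
    mu, sig, sigp = _coeffs(y, theta, model)
    return milstein_support_bound_coeffs(y, dt, float(mu), float(sig), float(sigp))


def milstein_terms(y_next, y, dt, theta, model: DiffusionModel) -> MilsteinDensityTerms:
    """The (A, C, D) terms and support bound for a single transition."""
    mu, sig, sigp = (float(v) for v in _coeffs(y, theta, model))
    s = sig * sigp
    A = sig * sig + 2.0 * s * (float(y_next) - float(y) - (mu - 0.5 * s) * float(dt))
    if abs(A) < _A_CLIP * sig * sig:
        A = 0.0
    C = sig + sigp * (float(y_next) - float(y) - (mu - 0.5 * s) * float(dt))
    D = sig * sigp * sigp * float(dt)
    bound, kind = milstein_support_bound_coeffs(y, dt, mu, sig, sigp)
    return MilsteinDensityTerms(A=A, C=C, D=D, bound=bound, bound_kind=kind)


# ---------------------------------------------------------------------------
# kernel registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionKernel:
    """A named (log_density, sample, support_bound) triple for one scheme."""

    name: str
    log_density: Callable  # (y_next, y, dt, theta, model) -> log-density
    sample: Callable       # (y, dt, theta, model, rng, size=None) -> state
    support_bound: Optional[Callable] = None


def _euler_sample(y, dt, theta, model, rng, size=None):
    return euler_step_sample(y, dt, theta, model, rng=rng, size=size)


def _milstein_sample(y, dt, theta, model, rng, size=None):
    return milstein_step_sample(y, dt, theta, model, rng=rng, size=size)


def _no_bound(y, dt, theta, model):
    return -math.inf, "none"


_EULER = TransitionKernel("euler", euler_log_density, _euler_sample, _no_bound)
_MILSTEIN = TransitionKernel("milstein", milstein_log_density, _milstein_sample, milstein_support_bound)


def get_kernel(name: str, model: Optional[DiffusionModel] = None) -> TransitionKernel:
    """Kernel registry: ``"euler"``, ``"milstein"`` or ``"exact"`` (the latter
    requires a model carrying a closed-form transition law)."""
    name = name.lower()
    if name == "euler":
        return _EULER
    if name == "milstein":
        return _MILSTEIN
    if name == "exact":
        if model is None or model.exact_log_density is None:
            raise ValueError("exact kernel requires a model with a closed-form transition density")

        exact_model = model

        def log_density(y_next, y, dt, theta, model=None):
            return exact_model.exact_log_density(y, y_next, dt, theta)

        def sample(y, dt, theta, model, rng, size=None):
            return exact_model.exact_sampler(y, dt, theta, rng, size=size)

        return TransitionKernel("exact", log_density, sample, _no_bound)
    raise KeyError(f"unknown scheme {name!r}; available: euler, milstein, exact")
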