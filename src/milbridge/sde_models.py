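"""Diffusion-model abstractions and concrete 1-d models.

A :class:`DiffusionModel` bundles the drift and diffusion functions of the
Itô SDE

    dX_t = mu(X_t, theta) dt + sigma(X_t, theta) dB_t,

together with the analytic state-derivative of the diffusion function (needed
by the Milstein scheme), the lower boundary of the state space, and — when the
SDE has a closed-form solution — the exact transition density and sampler.

Two concrete models are provided: geometric Brownian motion (GBM), whose
lognormal transition law is used both to generate synthetic data and as the
exact-likelihood benchmark, and the Cox–Ingersoll–Ross (CIR) square-root
process.  Parameters are passed around as plain sequences ``theta``; for the
GBM ``theta = (alpha, sigma2)`` where ``sigma2`` is the *squared* diffusion
coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "DiffusionModel",
    "GBMParams",
    "gbm_model",
    "cir_model",
    "get_model",
    "gbm_exact_transition_density",
    "gbm_exact_transition_log_density",
    "gbm_exact_sample",
    "milstein_applicable",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class DiffusionModel:
    """A 1-d time-homogeneous Itô diffusion.

    ``drift``, ``diffusion`` and ``diffusion_dy`` are callables of
    ``(state, theta)`` and must accept NumPy arrays for ``state``.
    ``diffusion_dy`` is the analytic derivative of ``diffusion`` with respect
    to the state variable.  ``positive_params`` flags, per component of
    ``theta``, whether the component lives on the positive half line (these
    components receive lognormal random-walk proposals in the sampler, the
    others Gaussian ones).

    ``exact_log_density(x, y, dt, theta)`` — when available — is the log
    transition density of ``X_{s+dt} = y`` given ``X_s = x``;
    ``exact_sampler(x, dt, theta, rng)`` draws from the same law.
    """

    name: str
    drift: Callable
    diffusion: Callable
    diffusion_dy: Callable
    state_lower: float = -math.inf
    positive_params: tuple = ()
    exact_log_density: Optional[Callable] = None
    exact_sampler: Optional[Callable] = None
    # optional multi-dimensional interface used only by milstein_applicable
    dim: int = 1
    diffusion_matrix: Optional[Callable] = None
    diffusion_jacobian: Optional[Callable] = None

    def in_state_space(self, y) -> np.ndarray:
        return np.asarray(y) > self.state_lower if np.isfinite(self.state_lower) else np.isfinite(y)


@dataclass(frozen=True)
class GBMParams:
    """Parameters of the GBM, ``dX = alpha X dt + sigma X dB`` with
    ``sigma2 = sigma**2``."""

    alpha: float
    sigma2: float

    def __post_init__(self):
        if not self.sigma2 > 0:
            raise ValueError(f"sigma2 must be strictly positive, got {self.sigma2}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.sigma2], dtype=float)


def _theta_gbm(theta) -> tuple:
    if isinstance(theta, GBMParams):
        return theta.alpha, theta.sigma2
    alpha, sigma2 = float(theta[0]), float(theta[1])
    return alpha, sigma2


def gbm_exact_transition_log_density(x, y, dt, theta):
    """Log transition density of the GBM, ``log p(X_{s+dt}=y | X_s=x)``.

    The multiplicative increment ``y/x`` is lognormal with log-mean
    ``(alpha - sigma2/2) dt`` and log-variance ``sigma2 dt``.  Returns
    ``-inf`` for ``y <= 0`` (outside the state space); raises for
    non-positive ``x`` or ``dt``.
    """
    alpha, sigma2 = _theta_gbm(theta)
    x = np.asarray(x, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(x <= 0):
        raise ValueError("conditioning state x must be strictly positive for the GBM")
    if np.any(dt <= 0):
        raise ValueError("time step dt must be strictly positive")
    y = np.asarray(y, dtype=float)
    v = sigma2 * dt
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log(np.where(y > 0, y, np.nan)) - np.log(x) - (alpha - 0.5 * sigma2) * dt
        lp = -0.5 * (_LOG_2PI + np.log(v)) - np.log(np.where(y > 0, y, np.nan)) - 0.5 * z * z / v
    lp = np.where(y > 0, lp, -np.inf)
    return lp if lp.ndim else float(lp)


def gbm_exact_transition_density(x, y, dt, theta):
    """Transition density of the GBM; zero for ``y <= 0``."""
    lp = gbm_exact_transition_log_density(x, y, dt, theta)
    return np.exp(lp)


def gbm_exact_sample(x, dt, theta, rng, size=None):
    """Draw ``X_{s+dt}`` given ``X_s = x`` from the exact lognormal law."""
    alpha, sigma2 = _theta_gbm(theta)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("conditioning state x must be strictly positive for the GBM")
    if not np.all(np.asarray(dt) > 0):
        raise ValueError("time step dt must be strictly positive")
    dt = np.asarray(dt, dtype=float)
    z = rng.normal(size=size if size is not None else np.broadcast_shapes(x.shape, dt.shape))
    out = x * np.exp((alpha - 0.5 * sigma2) * dt + np.sqrt(sigma2 * dt) * z)
    return out if out.ndim else float(out)


def gbm_model() -> DiffusionModel:
    """GBM: drift ``alpha*y``, diffusion ``sqrt(sigma2)*y``, state space (0, inf)."""

    def drift(y, theta):
        alpha, _ = _theta_gbm(theta)
        return alpha * np.asarray(y, dtype=float)

    def diffusion(y, theta):
        _, sigma2 = _theta_gbm(theta)
        return math.sqrt(sigma2) * np.asarray(y, dtype=float)

    def diffusion_dy(y, theta):
        _, sigma2 = _theta_gbm(theta)
        return math.sqrt(sigma2) * np.ones_like(np.asarray(y, dtype=float))

    return DiffusionModel(
        name="gbm",
        drift=drift,
        diffusion=diffusion,
        diffusion_dy=diffusion_dy,
        state_lower=0.0,
        positive_params=(False, True),
        exact_log_density=gbm_exact_transition_log_density,
        exact_sampler=gbm_exact_sample,
    )


def cir_model() -> DiffusionModel:
    """CIR square-root process ``dX = beta (kappa - X) dt + sigma sqrt(X) dB``
    with ``theta = (beta, kappa, sigma)`` and state space (0, inf).

    No closed-form transition sampler is attached; the model is inferred with
    the scheme-based kernels only.
    """

    def drift(y, theta):
        beta, kappa = float(theta[0]), float(theta[1])
        return beta * (kappa - np.asarray(y, dtype=float))

    def diffusion(y, theta):
        sigma = float(theta[2])
        return sigma * np.sqrt(np.asarray(y, dtype=float))

    def diffusion_dy(y, theta):
        sigma = float(theta[2])
        return 0.5 * sigma / np.sqrt(np.asarray(y, dtype=float))

    return DiffusionModel(
        name="cir",
        drift=drift,
        diffusion=diffusion,
        diffusion_dy=diffusion_dy,
        state_lower=0.0,
        positive_params=(True, True, True),
    )


_MODELS = {"gbm": gbm_model, "cir": cir_model}


def get_model(name: str) -> DiffusionModel:
    """Look up a model constructor by name (``"gbm"`` or ``"cir"``)."""
    try:
        return _MODELS[name.lower()]()
    except KeyError:
        raise KeyError(f"unknown model {name!r}; available: {sorted(_MODELS)}") from None


def milstein_applicable(model: DiffusionModel, probe_states: Sequence, theta, atol: float = 1e-10) -> bool:
    """Whether the closed-form Milstein transition density applies to ``model``.

    All scalar (1-d, one Brownian motion) diffusions qualify.  For a model
    exposing the optional matrix interface the commutativity condition
    ``sigma_rj * d sigma_il / d y_r = 0`` for ``j != l`` is checked
    numerically at the probe states.
    """
    if model.dim == 1 or model.diffusion_matrix is None:
        return True
    for y in probe_states:
        sig = np.atleast_2d(model.diffusion_matrix(y, theta))
        jac = np.asarray(model.diffusion_jacobian(y, theta))  # (d, q, d)
        d, q = sig.shape
        for j in range(q):
            for ll in range(q):
                if j == ll:
                    continue
                for i in range(d):
                    for r in range(d):
                        if abs(sig[r, j] * jac[i, ll, r]) > atol:
                            return False
    return True
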