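"""Path-proposal distributions for the data-augmentation path update.

A path segment between two fixed anchors is refreshed one point at a time,
left to right.  Each single-point proposal is described by a
:class:`SegmentProposalTask`: the current left conditioning value, the fixed
right anchor, the step ``dt_step`` to the proposed point and the remaining
time ``dt_plus`` from the proposed point to the anchor.

Implemented proposal families (registry :data:`PROPOSALS`):

``lc-euler`` / ``lc-milstein``
    Left-conditioned: draw from the one-step scheme kernel, ignoring the
    right anchor.  Cheap but blind to the anchor, hence low acceptance.

``mbe``
    Modified bridge based on the Euler scheme (Durham–Gallant): a Gaussian
    with mean on the straight line to the anchor and variance
    ``(dt_plus / (dt_step + dt_plus)) * sigma(left)^2 * dt_step``, i.e. with
    the drift/diffusion of the *left* point substituted for those of the
    proposed point.

``mbm``
    Modified bridge based on the Milstein scheme: the product of the Milstein
    density of the point given the left value and the Milstein density of the
    anchor given the point (no substitution).  The product has no closed-form
    normalization; it is normalized by numerical quadrature over the feasible
    set and sampled by rejection from a rectangle envelope.  When the
    feasible set is empty the caller falls back to the ``mbe`` proposal for
    that point (with the Euler proposal-density factor), which is counted.

``dbm``
    Diffusion-bridge Milstein: the closed-form Milstein kernel evaluated with
    the bridge-SDE coefficients ``mu -> (right-left)/t_remaining`` and
    ``sigma -> sqrt(dt_plus/t_remaining) * sigma(left)`` (and the analogous
    derivative).  Direct sampling, no normalization needed.

Proposed points outside the state space (possible for the Gaussian families)
are re-drawn; every re-draw is counted but the proposal density is *not*
renormalized for the truncation, matching the procedure the estimates are
defined with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .sde_models import DiffusionModel
from .transition_kernels import (
    euler_log_density_coeffs,
    get_kernel,
    milstein_log_density,
    milstein_log_density_coeffs,
    milstein_step_coeffs,
    milstein_support_bound,
)

__all__ = [
    "SegmentProposalTask",
    "FeasibleSet",
    "EmptyFeasibleSetError",
    "NumericalFailureError",
    "ChainStateError",
    "PROPOSALS",
    "lc_propose",
    "lc_log_q",
    "lc_segment_log_accept",
    "mbe_propose",
    "mbe_log_q",
    "mbm_feasible_set",
    "mbm_unnormalized_log_density",
    "normalize_on_interval",
    "mbm_propose",
    "mbm_log_q",
    "dbm_propose",
    "dbm_log_q",
    "propose_segment",
    "segment_log_q",
    "segment_log_target",
    "segment_log_accept",
]

_MAX_REDRAWS = 1000
_MAX_REJECTION_DRAWS = 1_000_000
_LOG_TRUNC = 20.0 * math.log(10.0)   # density support truncated at 1e-20 * max
_LOG_EXTEND = 30.0 * math.log(10.0)  # infinite-bound truncation at 1e-30 * max
_ENVELOPE_INFLATION = 1.05


class EmptyFeasibleSetError(RuntimeError):
    """The Milstein modified-bridge feasible set is empty; fall back to the
    Euler-based proposal for this point."""


class NumericalFailureError(RuntimeError):
    """Quadrature or rejection sampling failed beyond recovery."""


class ChainStateError(RuntimeError):
    """The current chain state has zero target or proposal density."""


@dataclass(frozen=True)
class SegmentProposalTask:
    """One single-point proposal within a bridge segment."""

    left_value: float
    right_value: float
    dt_step: float
    dt_plus: float
    theta: object
    model: DiffusionModel

    def __post_init__(self):
        if not self.dt_step > 0:
            raise ValueError("dt_step must be positive")
        if self.dt_plus < 0:
            raise ValueError("dt_plus must be non-negative")

    @property
    def t_remaining(self) -> float:
        return self.dt_step + self.dt_plus


@dataclass(frozen=True)
class FeasibleSet:
    """Interval of admissible proposal values; ``empty`` iff lower > upper."""

    lower: float
    upper: float

    @property
    def empty(self) -> bool:
        return self.lower > self.upper


def _count(counters, key):
    if counters is not None:
        counters[key] = counters.get(key, 0) + 1


# ---------------------------------------------------------------------------
# left-conditioned proposal
# ---------------------------------------------------------------------------

def lc_propose(task: SegmentProposalTask, scheme: str, rng, counters=None):
    """Draw from the one-step kernel conditioned on the left value only."""
    kernel = get_kernel(scheme, task.model)
    for _ in range(_MAX_REDRAWS):
        point = float(kernel.sample(task.left_value, task.dt_step, task.theta, task.model, rng))
        if point > task.model.state_lower:
            return point, float(kernel.log_density(point, task.left_value, task.dt_step, task.theta, task.model))
        _count(counters, "negative_redraws")
    raise NumericalFailureError("left-conditioned proposal: too many out-of-state-space re-draws")


def lc_log_q(point, task: SegmentProposalTask, scheme: str):
    kernel = get_kernel(scheme, task.model)
    return float(kernel.log_density(point, task.left_value, task.dt_step, task.theta, task.model))


def lc_segment_log_accept(times, v_new, v_old, theta, model, scheme: str):
    """Reduced acceptance for the left-conditioned proposal: all factors but
    the final-step transition densities cancel."""
    kernel = get_kernel(scheme, model)
    dt_last = float(times[-1] - times[-2])
    lp_new = float(kernel.log_density(v_new[-1], v_new[-2], dt_last, theta, model))
    lp_old = float(kernel.log_density(v_old[-1], v_old[-2], dt_last, theta, model))
    if lp_old == -math.inf:
        raise ChainStateError("current segment has zero density at the final step")
    return min(0.0, lp_new - lp_old)


# ---------------------------------------------------------------------------
# modified bridge, Euler scheme (Durham--Gallant)
# ---------------------------------------------------------------------------

def _mbe_moments(task: SegmentProposalTask):
    tr = task.t_remaining
    mean = task.left_value + (task.right_value - task.left_value) * task.dt_step / tr
    sig_left = float(task.model.diffusion(task.left_value, task.theta))
    var = (task.dt_plus / tr) * sig_left ** 2 * task.dt_step
    return mean, var


def mbe_propose(task: SegmentProposalTask, rng, counters=None):
    """Gaussian modified-bridge draw; out-of-state-space points are re-drawn
    (counted, density not renormalized)."""
    mean, var = _mbe_moments(task)
    if var <= 0:
        raise ValueError("degenerate modified-bridge proposal: dt_plus = 0")
    sd = math.sqrt(var)
    for _ in range(_MAX_REDRAWS):
        point = mean + sd * float(rng.standard_normal())
        if point > task.model.state_lower:
            return point, _normal_logpdf(point, mean, var)
        _count(counters, "negative_redraws")
    raise NumericalFailureError("modified-bridge proposal: too many out-of-state-space re-draws")


def mbe_log_q(point, task: SegmentProposalTask):
    mean, var = _mbe_moments(task)
    return _normal_logpdf(float(point), mean, var)


def _normal_logpdf(x, mean, var):
    return -0.5 * (math.log(2.0 * math.pi * var) + (x - mean) ** 2 / var)


# ---------------------------------------------------------------------------
# modified bridge, Milstein scheme
# ---------------------------------------------------------------------------

def mbm_feasible_set(task: SegmentProposalTask) -> FeasibleSet:
    """Intersection of the supports of the two Milstein factors with the
    state space.

    The first factor (point given left value) contributes the lower support
    bound of the Milstein kernel started at the left value.  The second
    factor (anchor given point) requires ``E >= 0``; for the GBM this is
    solvable in closed form and yields an upper bound ``right / c`` when
    ``c = 1/2 + (alpha - sigma2/2) dt_plus > 0`` (Case I), a (negative, hence
    inactive) lower bound ``right / c`` when ``c < 0`` (Case II) and no
    constraint when ``c = 0`` (Case III).
    """
    model, theta = task.model, task.theta
    sigp = float(model.diffusion_dy(task.left_value, theta))
    if sigp == 0.0:
        lo = model.state_lower if math.isfinite(model.state_lower) else -math.inf
        return FeasibleSet(lo, math.inf)
    if model.name != "gbm":
        raise NotImplementedError(
            "the Milstein modified-bridge feasible set is implemented for the GBM "
            "(and for state-independent-diffusion models, where it is unconstrained)"
        )
    alpha, sigma2 = float(theta[0]), float(theta[1])
    l_1st, kind = milstein_support_bound(task.left_value, task.dt_step, theta, model)
    assert kind == "lower"
    lower = max(0.0, l_1st)
    c = 0.5 + (alpha - 0.5 * sigma2) * task.dt_plus
    if c > 0.0:  # Case I
        upper = task.right_value / c
    elif c < 0.0:  # Case II
        lower = max(lower, task.right_value / c)
        upper = math.inf
    else:  # Case III
        upper = math.inf
    return FeasibleSet(lower, upper)


def mbm_unnormalized_log_density(point, task: SegmentProposalTask):
    """Log of the product of the two Milstein factors; ``-inf`` outside the
    feasible set.  Vectorized over ``point``."""
    point = np.asarray(point, dtype=float)
    model, theta = task.model, task.theta
    lp1 = milstein_log_density(point, task.left_value, task.dt_step, theta, model)
    ok = point > model.state_lower
    safe = np.where(ok, point, task.left_value)
    mu = model.drift(safe, theta)
    sig = model.diffusion(safe, theta)
    sigp = model.diffusion_dy(safe, theta)
    lp2 = milstein_log_density_coeffs(task.right_value, safe, task.dt_plus, mu, sig, sigp)
    out = np.where(ok, lp1 + lp2, -np.inf)
    return out if out.ndim else float(out)


def _scalar_mbm_log_f(point: float, task: SegmentProposalTask) -> float:
    """Scalar-path evaluation used where exact float agreement with the
    target-density sum matters (the acceptance-ratio cancellation)."""
    model, theta = task.model, task.theta
    if point <= model.state_lower:
        return -math.inf
    lp1 = milstein_log_density(point, task.left_value, task.dt_step, theta, model)
    lp2 = milstein_log_density(task.right_value, point, task.dt_plus, theta, model)
    return lp1 + lp2


def _bracket_max(log_f: Callable, lower: float, upper: float, scale: float, n_grid: int = 512):
    """Locate the maximum of ``exp(log_f)`` on (lower, upper) and the
    sub-interval carrying all values above ``1e-20 * max``.

    A grid (log-spaced when the interval is positive) seeds a bounded scalar
    optimization; infinite bounds are truncated where the density falls below
    ``1e-30`` of the running grid maximum.
    """
    if not lower < upper:
        raise EmptyFeasibleSetError("empty interval")
    span_scale = max(abs(scale), 1e-12)
    if math.isinf(upper):
        hi = max(4.0 * span_scale, 2.0 * lower + span_scale)
        best = -math.inf
        for _ in range(120):
            val = float(log_f(hi))
            best = max(best, val)
            if val < best - _LOG_EXTEND and hi > 4.0 * span_scale:
                break
            hi *= 1.6
        upper = hi
    if math.isinf(lower):
        lo = min(-4.0 * span_scale, 2.0 * upper - span_scale)
        best = -math.inf
        for _ in range(120):
            val = float(log_f(lo))
            best = max(best, val)
            if val < best - _LOG_EXTEND and lo < -4.0 * span_scale:
                break
            lo *= 1.6
        lower = lo
    pad = 1e-9 * (upper - lower)
    a, b = lower + pad, upper - pad
    if lower > 0:
        grid = np.geomspace(a, b, n_grid)
    else:
        grid = np.linspace(a, b, n_grid)
    vals = np.asarray(log_f(grid), dtype=float)
    # a grid point may fall on a support boundary where the density has an
    # integrable singularity; exclude such points from the maximum search
    vals = np.where(np.isinf(vals) & (vals > 0), -np.inf, vals)
    if not np.any(np.isfinite(vals)):
        raise NumericalFailureError("proposal density vanished on the whole search grid")
    j = int(np.nanargmax(vals))
    lo_b, hi_b = grid[max(j - 1, 0)], grid[min(j + 1, n_grid - 1)]
    res = minimize_scalar(lambda x: -float(log_f(x)), bounds=(lo_b, hi_b), method="bounded")
    x_max, log_fmax = float(res.x), float(-res.fun)
    if vals[j] > log_fmax:
        x_max, log_fmax = float(grid[j]), float(vals[j])
    keep = np.where(vals >= log_fmax - _LOG_TRUNC)[0]
    i0, i1 = int(keep[0]), int(keep[-1])
    lo_t = grid[max(i0 - 1, 0)]
    hi_t = grid[min(i1 + 1, n_grid - 1)]
    return x_max, log_fmax, float(lo_t), float(hi_t)


def normalize_on_interval(log_f: Callable, fset: FeasibleSet, scale: Optional[float] = None):
    """Normalization constant of an unnormalized density on an interval.

    Returns ``(log_Z, (lo, hi))`` where the integration interval is restricted
    to the region with density at least ``1e-20`` of its maximum and the
    integrand is rescaled by the maximum before quadrature.
    """
    if fset.empty:
        raise EmptyFeasibleSetError("cannot normalize on an empty feasible set")
    if scale is None:
        finite = [abs(v) for v in (fset.lower, fset.upper) if math.isfinite(v) and v != 0]
        scale = max(finite) if finite else 1.0
    _, log_fmax, lo_t, hi_t = _bracket_max(log_f, fset.lower, fset.upper, scale)

    def integrand(x):
        v = float(log_f(x)) - log_fmax
        return math.exp(v) if v > -745.0 else 0.0

    val, _err = quad(integrand, lo_t, hi_t, limit=200)
    if not val > 0 or not math.isfinite(val):
        raise NumericalFailureError("normalization integral underflowed to zero")
    return log_fmax + math.log(val), (lo_t, hi_t)


def mbm_propose(task: SegmentProposalTask, rng, counters=None, normalize=True, zcache=None):
    """Rejection-sample from the Milstein modified-bridge density.

    ``(u1, u2)`` is drawn uniformly from ``I x (0, d_max)`` and ``u1`` is
    accepted when ``u2 <= f(u1)``; the envelope height is the numerically
    located maximum inflated by 5 per cent.  Raises
    :class:`EmptyFeasibleSetError` when the feasible set is empty (the caller
    then substitutes the ``mbe`` proposal).
    """
    fset = mbm_feasible_set(task)
    if fset.empty:
        raise EmptyFeasibleSetError("empty Milstein modified-bridge feasible set")
    scale = max(abs(task.left_value), abs(task.right_value), 1e-12)
    log_f = lambda x: mbm_unnormalized_log_density(x, task)
    _, log_fmax, lo_t, hi_t = _bracket_max(log_f, fset.lower, fset.upper, scale)
    log_env = log_fmax + math.log(_ENVELOPE_INFLATION)
    batch = 64
    for _ in range(_MAX_REJECTION_DRAWS // batch + 1):
        u1 = rng.uniform(lo_t, hi_t, size=batch)
        u2 = rng.uniform(0.0, 1.0, size=batch)
        logs = np.asarray(log_f(u1), dtype=float)
        acc = np.log(u2) + log_env <= logs
        if np.any(acc):
            point = float(u1[np.argmax(acc)])
            return point, mbm_log_q(point, task, normalize=normalize, zcache=zcache)
    raise NumericalFailureError("Milstein modified-bridge rejection sampling did not accept")


def _mbm_log_norm(task: SegmentProposalTask, zcache=None) -> float:
    key = (task.left_value, task.right_value, task.dt_step, task.dt_plus)
    if zcache is not None and key in zcache:
        return zcache[key]
    fset = mbm_feasible_set(task)
    scale = max(abs(task.left_value), abs(task.right_value), 1e-12)
    log_z, _ = normalize_on_interval(lambda x: mbm_unnormalized_log_density(x, task), fset, scale)
    if zcache is not None:
        zcache[key] = log_z
    return log_z


def mbm_log_q(point, task: SegmentProposalTask, normalize=True, zcache=None):
    """Log proposal density of the Milstein modified bridge; normalized by
    quadrature unless ``normalize=False`` (legitimate in acceptance ratios
    whose normalization constants cancel)."""
    lq = _scalar_mbm_log_f(float(point), task)
    if not normalize or lq == -math.inf:
        return lq
    return lq - _mbm_log_norm(task, zcache=zcache)


# ---------------------------------------------------------------------------
# diffusion-bridge Milstein
# ---------------------------------------------------------------------------

def _dbm_coeffs(task: SegmentProposalTask):
    tr = task.t_remaining
    ratio = math.sqrt(task.dt_plus / tr)
    mu = (task.right_value - task.left_value) / tr
    sig = ratio * float(task.model.diffusion(task.left_value, task.theta))
    sigp = ratio * float(task.model.diffusion_dy(task.left_value, task.theta))
    return mu, sig, sigp


def dbm_propose(task: SegmentProposalTask, rng, counters=None):
    """Draw from the Milstein kernel with bridge-substituted coefficients
    (drift toward the anchor, diffusion shrunk by ``sqrt(dt_plus/t_rem)``)."""
    if task.dt_plus == 0:
        return task.right_value, 0.0
    mu, sig, sigp = _dbm_coeffs(task)
    for _ in range(_MAX_REDRAWS):
        db = math.sqrt(task.dt_step) * float(rng.standard_normal())
        point = float(milstein_step_coeffs(task.left_value, task.dt_step, mu, sig, sigp, db))
        if point > task.model.state_lower:
            return point, float(
                milstein_log_density_coeffs(point, task.left_value, task.dt_step, mu, sig, sigp)
            )
        _count(counters, "negative_redraws")
    raise NumericalFailureError("diffusion-bridge proposal: too many out-of-state-space re-draws")


def dbm_log_q(point, task: SegmentProposalTask):
    mu, sig, sigp = _dbm_coeffs(task)
    return float(milstein_log_density_coeffs(float(point), task.left_value, task.dt_step, mu, sig, sigp))


def dbm_support_bound(task: SegmentProposalTask):
    """Support bound of the substituted kernel (for diagnostics/tests)."""
    from .transition_kernels import milstein_support_bound_coeffs

    mu, sig, sigp = _dbm_coeffs(task)
    return milstein_support_bound_coeffs(task.left_value, task.dt_step, mu, sig, sigp)


# ---------------------------------------------------------------------------
# segment-level operations
# ---------------------------------------------------------------------------

def _point_propose(task, kind, rng, counters, normalize, zcache):
    if kind == "mbe":
        return mbe_propose(task, rng, counters)
    if kind == "dbm":
        return dbm_propose(task, rng, counters)
    if kind == "mbm":
        try:
            return mbm_propose(task, rng, counters, normalize=normalize, zcache=zcache)
        except EmptyFeasibleSetError:
            _count(counters, "euler_fallbacks")
            return mbe_propose(task, rng, counters)
    if kind in ("lc-euler", "lc-milstein"):
        return lc_propose(task, kind.split("-")[1], rng, counters)
    raise KeyError(f"unknown proposal kind {kind!r}")


def _point_log_q(point, task, kind, counters, normalize, zcache):
    if kind == "mbe":
        return mbe_log_q(point, task)
    if kind == "dbm":
        return dbm_log_q(point, task)
    if kind == "mbm":
        if mbm_feasible_set(task).empty:
            return mbe_log_q(point, task)
        return mbm_log_q(point, task, normalize=normalize, zcache=zcache)
    if kind in ("lc-euler", "lc-milstein"):
        return lc_log_q(point, task, kind.split("-")[1])
    raise KeyError(f"unknown proposal kind {kind!r}")


def _segment_tasks(times, values, theta, model):
    """Tasks for the interior points of one segment (anchors fixed)."""
    t = np.asarray(times, dtype=float)
    tasks = []
    for k in range(len(t) - 2):
        tasks.append(
            SegmentProposalTask(
                left_value=float(values[k]),
                right_value=float(values[-1]),
                dt_step=float(t[k + 1] - t[k]),
                dt_plus=float(t[-1] - t[k + 1]),
                theta=theta,
                model=model,
            )
        )
    return tasks


def propose_segment(times, v_old, theta, model, kind, rng, counters=None, normalize=None, zcache=None):
    """Propose all interior points of one segment, left to right.

    Returns ``(v_new, log_q_new)`` where ``v_new`` shares the anchors of
    ``v_old``.  ``normalize`` defaults to True exactly when the segment has
    more than one interior point (otherwise the modified-bridge normalization
    constants cancel in the acceptance ratio).
    """
    v_old = np.asarray(v_old, dtype=float)
    n_int = len(v_old) - 2
    if normalize is None:
        normalize = n_int > 1
    v_new = v_old.copy()
    log_q = 0.0
    t = np.asarray(times, dtype=float)
    for k in range(n_int):
        task = SegmentProposalTask(
            left_value=float(v_new[k]),
            right_value=float(v_new[-1]),
            dt_step=float(t[k + 1] - t[k]),
            dt_plus=float(t[-1] - t[k + 1]),
            theta=theta,
            model=model,
        )
        point, lq = _point_propose(task, kind, rng, counters, normalize, zcache)
        v_new[k + 1] = point
        log_q += lq
    return v_new, log_q


def segment_log_q(times, values, theta, model, kind, counters=None, normalize=None, zcache=None):
    """Log proposal density of the interior points of ``values`` under the
    sequential single-point proposal scheme ``kind``."""
    values = np.asarray(values, dtype=float)
    n_int = len(values) - 2
    if normalize is None:
        normalize = n_int > 1
    log_q = 0.0
    t = np.asarray(times, dtype=float)
    for k in range(n_int):
        task = SegmentProposalTask(
            left_value=float(values[k]),
            right_value=float(values[-1]),
            dt_step=float(t[k + 1] - t[k]),
            dt_plus=float(t[-1] - t[k + 1]),
            theta=theta,
            model=model,
        )
        log_q += _point_log_q(float(values[k + 1]), task, kind, counters, normalize, zcache)
    return log_q


def segment_log_target(times, values, theta, model, scheme: str):
    """Sum of one-step log transition densities along the segment."""
    kernel = get_kernel(scheme, model)
    t = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    total = 0.0
    for k in range(len(values) - 1):
        total += float(kernel.log_density(values[k + 1], values[k], float(t[k + 1] - t[k]), theta, model))
    return total


def segment_log_accept(
    new, old, times, theta, model, likelihood_scheme: str, proposal_kind: str,
    counters=None, zcache=None, normalize=None,
):
    """Log Metropolis–Hastings acceptance for one or several independent
    segments updated collectively.

    ``new``/``old``/``times`` may be single arrays (one segment) or lists of
    arrays (several segments between observations); in the latter case the
    independent per-segment log ratios are summed.
    """
    if isinstance(times, (list, tuple)):
        total = 0.0
        for t_i, n_i, o_i in zip(times, new, old):
            total += _one_segment_log_ratio(
                n_i, o_i, t_i, theta, model, likelihood_scheme, proposal_kind, counters, zcache, normalize
            )
        return min(0.0, total)
    return min(
        0.0,
        _one_segment_log_ratio(new, old, times, theta, model, likelihood_scheme, proposal_kind, counters, zcache, normalize),
    )


def _one_segment_log_ratio(new, old, times, theta, model, scheme, kind, counters, zcache, normalize):
    t_old = segment_log_target(times, old, theta, model, scheme)
    if t_old == -math.inf:
        raise ChainStateError("current segment has zero target density")
    q_new = segment_log_q(times, new, theta, model, kind, counters, normalize, zcache)
    q_old = segment_log_q(times, old, theta, model, kind, counters, normalize, zcache)
    t_new = segment_log_target(times, new, theta, model, scheme)
    # grouped so that shared terms cancel exactly in floating point
    return (t_new - q_new) - (t_old - q_old)


@dataclass(frozen=True)
class ProposalFamily:
    name: str
    propose: Callable
    log_q: Callable


PROPOSALS = {
    "mbe": ProposalFamily("mbe", mbe_propose, mbe_log_q),
    "mbm": ProposalFamily("mbm", mbm_propose, mbm_log_q),
    "dbm": ProposalFamily("dbm", dbm_propose, dbm_log_q),
    "lc-euler": ProposalFamily(
        "lc-euler",
        lambda task, rng, counters=None: lc_propose(task, "euler", rng, counters),
        lambda point, task: lc_log_q(point, task, "euler"),
    ),
    "lc-milstein": ProposalFamily(
        "lc-milstein",
        lambda task, rng, counters=None: lc_propose(task, "milstein", rng, counters),
        lambda point, task: lc_log_q(point, task, "milstein"),
    ),
}
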