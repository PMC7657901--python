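"""Independent oracles used by the tests.

These deliberately re-derive quantities through routes different from the
package implementation: brute-force density products, closed-form Gaussian
transformations and grid quadrature.
"""

import math

import numpy as np
from scipy import stats


def milstein_density_two_root(y_next, y, dt, mu, sig, sigp):
    """Milstein one-step density via the change-of-variables formula:
    sum over the two Brownian-increment roots of phi(b; 0, dt) / |g'(b)|."""
    s = sig * sigp
    if s == 0.0:
        return stats.norm.pdf(y_next, loc=y + mu * dt, scale=abs(sig) * math.sqrt(dt))
    A = sig * sig + 2.0 * s * (y_next - y - (mu - 0.5 * s) * dt)
    if A < 0:
        return 0.0
    total = 0.0
    for sign in (+1.0, -1.0):
        b = (-sig + sign * math.sqrt(A)) / s
        total += stats.norm.pdf(b, scale=math.sqrt(dt)) / math.sqrt(A)
    return total


def milstein_cdf(z, y, dt, mu, sig, sigp):
    """Closed-form CDF of the Milstein one-step law (quadratic map of a
    Gaussian increment).  Assumes sig*sigp > 0 (upward parabola)."""
    s = sig * sigp
    A = sig * sig + 2.0 * s * (z - y - (mu - 0.5 * s) * dt)
    if A < 0:
        return 0.0
    sd = math.sqrt(dt)
    b_hi = (-sig + math.sqrt(A)) / s
    b_lo = (-sig - math.sqrt(A)) / s
    return stats.norm.cdf(b_hi, scale=sd) - stats.norm.cdf(b_lo, scale=sd)


def gbm_quadrature_posterior_mean(times, values, scheme, n_a=301, n_s=451,
                                  a_range=(-6.0, 8.0), s_range=(0.05, 14.0)):
    """Posterior mean of (alpha, sigma2) by 2-d grid quadrature under the
    study priors alpha ~ N(0,10), sigma2 ~ IG(2,2)."""
    dts = np.diff(times)
    y0 = values[:-1]
    y1 = values[1:]
    A = np.linspace(*a_range, n_a)
    S = np.linspace(*s_range, n_s)
    AA, SS = np.meshgrid(A, S, indexing="ij")
    ll = np.zeros_like(AA)
    for k in range(len(dts)):
        if scheme == "euler":
            var = SS * y0[k] ** 2 * dts[k]
            z = y1[k] - y0[k] - AA * y0[k] * dts[k]
            ll += -0.5 * np.log(2 * np.pi * var) - 0.5 * z * z / var
        elif scheme == "exact":
            v = SS * dts[k]
            z = np.log(y1[k]) - np.log(y0[k]) - (AA - 0.5 * SS) * dts[k]
            ll += -0.5 * np.log(2 * np.pi * v) - np.log(y1[k]) - 0.5 * z * z / v
        else:
            raise ValueError(scheme)
    lp = ll + stats.norm.logpdf(AA, 0.0, math.sqrt(10.0)) + stats.invgamma.logpdf(SS, 2.0, scale=2.0)
    w = np.exp(lp - lp.max())
    w /= w.sum()
    return float((w * AA).sum()), float((w * SS).sum())


def batch_means_se(x, n_batches=40):
    """Monte Carlo standard error of the mean of a correlated scalar chain."""
    x = np.asarray(x, dtype=float)
    b = len(x) // n_batches
    means = x[: n_batches * b].reshape(n_batches, b).mean(axis=1)
    return float(np.std(means, ddof=1) / math.sqrt(n_batches))
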