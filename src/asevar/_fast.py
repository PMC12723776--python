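"""Jitted likelihood kernels for the parametric bootstrap.

The bootstrap refits the per-gene BLN likelihood hundreds of times per gene;
these numba kernels reproduce :func:`asevar.bln._logpmf_arrays` (mu = 0,
mode-centered Gauss–Hermite) without array temporaries, plus a fixed-step
golden-section maximizer on log sigma.  The numpy implementation remains the
reference; equivalence is asserted in the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)
_HALF_LOG2 = 0.5 * math.log(2.0)
_GOLDEN = 0.6180339887498949


@njit(cache=False)
def neg_loglik(a, n, log_sigma, t, logw):  # pragma: no cover - exercised via wrappers
    sigma = math.exp(log_sigma)
    inv_v = 1.0 / (sigma * sigma)
    order = t.size
    vals = np.empty(order)
    total = 0.0
    for i in range(a.size):
        x = a[i]
        m = n[i]
        # Newton for the mode of x*d - m*softplus(d) - d^2/(2 sigma^2),
        # started from the Fisher-weighted shrunken logit of (x, m)
        ph = (x + 0.5) / (m + 1.0)
        info = (m + 1.0) * ph * (1.0 - ph)
        d = math.log(ph / (1.0 - ph)) * info / (info + inv_v)
        for _ in range(8):
            s = 1.0 / (1.0 + math.exp(-d))
            grad = x - m * s - d * inv_v
            hess = -m * s * (1.0 - s) - inv_v
            step = grad / hess
            if step > 4.0:
                step = 4.0
            elif step < -4.0:
                step = -4.0
            d -= step
        s = 1.0 / (1.0 + math.exp(-d))
        scale = 1.0 / math.sqrt(m * s * (1.0 - s) + inv_v)
        mx = -1e308
        for k in range(order):
            dk = d + _SQRT2 * scale * t[k]
            if dk > 0.0:
                lp = -math.log1p(math.exp(-dk))
                lq = lp - dk
            else:
                lq = -math.log1p(math.exp(dk))
                lp = lq + dk
            v = logw[k] + t[k] * t[k] + x * lp + (m - x) * lq - 0.5 * (dk / sigma) ** 2
            vals[k] = v
            if v > mx:
                mx = v
        acc = 0.0
        for k in range(order):
            acc += math.exp(vals[k] - mx)
        lcoef = math.lgamma(m + 1.0) - math.lgamma(x + 1.0) - math.lgamma(m - x + 1.0)
        total += lcoef - math.log(sigma) - _LOG_SQRT_2PI + mx + math.log(acc) + _HALF_LOG2 + math.log(scale)
    return -total


@njit(cache=False)
def fit_sigma(a, n, t, logw, log_lo, log_hi, iters):  # pragma: no cover
    lo = log_lo
    hi = log_hi
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1 = neg_loglik(a, n, x1, t, logw)
    f2 = neg_loglik(a, n, x2, t, logw)
    for _ in range(iters):
        if f1 < f2:
            hi = x2
            x2 = x1
            f2 = f1
            x1 = hi - _GOLDEN * (hi - lo)
            f1 = neg_loglik(a, n, x1, t, logw)
        else:
            lo = x1
            x1 = x2
            f1 = f2
            x2 = lo + _GOLDEN * (hi - lo)
            f2 = neg_loglik(a, n, x2, t, logw)
    return math.exp(0.5 * (lo + hi))


@njit(cache=False)
def bootstrap_fit(a_mat, n, t, logw, log_lo, log_hi, iters):  # pragma: no cover
    B = a_mat.shape[0]
    out = np.empty(B)
    for b in range(B):
        out[b] = fit_sigma(a_mat[b], n, t, logw, log_lo, log_hi, iters)
    return out
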