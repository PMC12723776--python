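"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: Monte-Carlo sampling
for BLN probabilities, the textbook step-up rule for BH, bisection tail
inversion for Clopper–Pearson, dense grid search for the sd_g MLE, and
explicit loops for joins/2x2 recounts.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom


def mc_bln_pmf(n: int, mu: float, sigma: float, draws: int, seed: int):
    """Monte-Carlo estimate of the BLN pmf with per-bin standard errors."""
    rng = np.random.default_rng(seed)
    delta = rng.normal(mu, sigma, size=draws)
    x = rng.binomial(n, 1.0 / (1.0 + np.exp(-delta)))
    freq = np.bincount(x, minlength=n + 1) / draws
    se = np.sqrt(freq * (1.0 - freq) / draws)
    return freq, se


def mc_bln_two_sided_p(x: int, n: int, sigma: float, draws: int, seed: int) -> float:
    """Monte-Carlo doubled-tail p-value under BLN(n, 0, sigma)."""
    rng = np.random.default_rng(seed)
    delta = rng.normal(0.0, sigma, size=draws)
    draws_x = rng.binomial(n, 1.0 / (1.0 + np.exp(-delta)))
    lower = np.mean(draws_x <= x)
    upper = np.mean(draws_x >= x)
    return min(1.0, 2.0 * min(lower, upper))


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH written directly from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return q


def bisect_clopper_pearson(k: int, m: int, level: float = 0.95, tol: float = 1e-11):
    """Exact CP interval by inverting binomial tails with bisection.

    low solves P(X >= k; p) = alpha/2 (0 when k = 0); high solves
    P(X <= k; p) = alpha/2 (1 when k = m).
    """
    alpha = 1.0 - level
    low, high = 0.0, 1.0
    if k > 0:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if binom.sf(k - 1, m, mid) < alpha / 2.0:  # P(X >= k) increasing in p
                lo = mid
            else:
                hi = mid
        low = 0.5 * (lo + hi)
    if k < m:
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if binom.cdf(k, m, mid) > alpha / 2.0:  # P(X <= k) decreasing in p
                lo = mid
            else:
                hi = mid
        high = 0.5 * (lo + hi)
    return low, high


def grid_search_sd(a: np.ndarray, n: np.ndarray, loglik_fn, n_grid: int = 2000,
                   lo: float = 1e-3, hi: float = 5.0) -> float:
    """Dense log-spaced grid maximizer of a per-gene likelihood."""
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))
    lls = [loglik_fn(a, n, s) for s in grid]
    return float(grid[int(np.argmax(lls))])
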