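"""Independent brute-force oracles used to validate the closed forms.

These deliberately avoid the package's marginal/truncated code paths: the
marginal oracle sums the conditional observed-length pmf against true-length
weights taken from scipy's distributions, extending the summation until the
neglected tail of P(N) is below 1e-12 of total mass.
"""

import numpy as np
from scipy import stats

from gctract.models import conditional_observed_pmf


def geom_weights(mean: float, nmax: int) -> np.ndarray:
    """P(N = n) for n = 1..nmax, N geometric with the given mean."""
    return stats.geom.pmf(np.arange(1, nmax + 1), 1.0 / mean)


def geom2_weights(gamma: float, nmax: int) -> np.ndarray:
    """P(N = n) for n = 1..nmax, N a sum of two geometrics with rate gamma."""
    n = np.arange(1, nmax + 1)
    # N - 2 is negative binomial (2 failures-before-successes convention)
    return stats.nbinom.pmf(n - 2, 2, gamma)


def adaptive_nmax(cdf_tail, start: int = 1000, tol: float = 1e-12) -> int:
    nmax = start
    while cdf_tail(nmax) > tol and nmax < 10_000_000:
        nmax *= 2
    return nmax


def brute_marginal(weight_fn, cdf_tail, l, psi: float) -> float:
    """sum_n P(L = l | N = n) P(N = n) with adaptive tail cutoff."""
    nmax = adaptive_nmax(cdf_tail)
    ns = np.arange(1, nmax + 1)
    w = weight_fn(nmax)
    return float((conditional_observed_pmf(np.full(ns.shape, l), ns, psi) * w).sum())


def brute_marginal_geom(mean: float, l, psi: float) -> float:
    return brute_marginal(
        lambda nmax: geom_weights(mean, nmax),
        lambda n: stats.geom.sf(n, 1.0 / mean), l, psi,
    )


def brute_marginal_geom2(gamma: float, l, psi: float) -> float:
    return brute_marginal(
        lambda nmax: geom2_weights(gamma, nmax),
        lambda n: stats.nbinom.sf(n - 2, 2, gamma), l, psi,
    )


def brute_marginal_mixture(phi1: float, phi2: float, w1: float, l, psi: float) -> float:
    return (w1 * brute_marginal_geom(phi1, l, psi)
            + (1.0 - w1) * brute_marginal_geom(phi2, l, psi))


def enumerate_conditional(l: int, n: int, psi: float) -> float:
    """P(L = l | N = n) by exhaustive enumeration of all 2^n conversion
    patterns on an n-bp tract, classified by the span of converted positions."""
    total = 0.0
    for mask in range(2 ** n):
        bits = [(mask >> k) & 1 for k in range(n)]
        k = sum(bits)
        if k == 0:
            span = 0
        else:
            idx = [i for i, b in enumerate(bits) if b]
            span = idx[-1] - idx[0] + 1
        if span == l:
            total += psi ** k * (1 - psi) ** (n - k)
    return total
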