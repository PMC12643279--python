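"""Tract-length models and observed-length distributions.

The true length ``N`` (bp) of a non-crossover gene conversion tract is modeled
as one of three families:

* :class:`Geometric` — ``N ~ Geometric`` on ``{1, 2, ...}`` with per-bp
  continuation-failure rate ``lam = 1/phi`` (mean ``phi``);
* :class:`TwoGeometric` — ``N`` is the sum of two i.i.d. geometrics on
  ``{2, 3, ...}``, each with rate ``gamma = 2/phi`` (tract grows outward in
  both directions from an initiation point);
* :class:`GeometricMixture` — a two-component mixture of geometrics with
  component means ``phi1 >= phi2`` and long-component weight ``w1``.

The observed length ``L`` is the inclusive span between the outermost
allele-converted positions of a tract. Conditional on ``N = n`` and a per-bp
allele conversion probability ``psi``::

    P(L = 0 | n) = (1 - psi)^n
    P(L = 1 | n) = n psi (1 - psi)^(n-1)
    P(L = l | n) = (n - l + 1) psi^2 (1 - psi)^(n-l),   2 <= l <= n

Marginalizing over each family gives closed forms (implemented in log space
below), and conditioning on ``lmin <= L <= lmax`` gives the truncated
distribution used for likelihood fitting. For the plain geometric family the
truncated form is free of ``psi``; for the other two families ``psi`` remains
in the likelihood through ``q = (1 - psi)(1 - rate)`` terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "Geometric",
    "TwoGeometric",
    "GeometricMixture",
    "TractLengthModel",
    "TruncationWindow",
    "conditional_observed_pmf",
    "marginal_pmf",
    "log_marginal_pmf",
    "truncated_pmf",
    "log_truncated_pmf",
    "model_mean",
]

_EPS = 1e-8


def _check_rate(rate: float, name: str) -> None:
    if not (0.0 < rate < 1.0):
        raise ValueError(f"{name} must lie in (0, 1), got {rate}")


@dataclass(frozen=True)
class Geometric:
    """Geometric tract length on {1, 2, ...}; ``rate`` is lambda = 1/phi."""

    rate: float

    def __post_init__(self) -> None:
        _check_rate(self.rate, "rate (lambda)")

    @property
    def mean(self) -> float:
        return 1.0 / self.rate

    n_params = 1


@dataclass(frozen=True)
class TwoGeometric:
    """Sum of two i.i.d. geometrics on {2, 3, ...}; ``rate`` is gamma = 2/phi.

    P(N = n) = (n - 1) gamma^2 (1 - gamma)^(n - 2) for n >= 2.
    """

    rate: float

    def __post_init__(self) -> None:
        _check_rate(self.rate, "rate (gamma)")

    @property
    def mean(self) -> float:
        return 2.0 / self.rate

    n_params = 1


@dataclass(frozen=True)
class GeometricMixture:
    """Two-component geometric mixture with component means (bp) and weight w1.

    ``mean1`` is by convention the long component and ``w1`` its mixing
    proportion; degenerate weights 0 and 1 are allowed and reduce the mixture
    to a single geometric.
    """

    mean1: float
    mean2: float
    w1: float

    def __post_init__(self) -> None:
        if self.mean1 < 1.0 or self.mean2 < 1.0:
            raise ValueError("component means must be >= 1 bp")
        if not (0.0 <= self.w1 <= 1.0):
            raise ValueError(f"w1 must lie in [0, 1], got {self.w1}")

    @property
    def mean(self) -> float:
        return self.w1 * self.mean1 + (1.0 - self.w1) * self.mean2

    n_params = 3


TractLengthModel = Union[Geometric, TwoGeometric, GeometricMixture]


@dataclass(frozen=True)
class TruncationWindow:
    """Retention band [lmin, lmax] (bp, inclusive) of observed lengths."""

    lmin: int = 2
    lmax: int = 1500

    def __post_init__(self) -> None:
        if not (1 <= self.lmin <= self.lmax):
            raise ValueError(f"require 1 <= lmin <= lmax, got {self}")

    def contains(self, l) -> np.ndarray:
        l = np.asarray(l)
        return (l >= self.lmin) & (l <= self.lmax)


def model_mean(model: TractLengthModel) -> float:
    """Mean true tract length phi in bp."""
    return model.mean


# ---------------------------------------------------------------------------
# Conditional distribution of L given N = n
# ---------------------------------------------------------------------------

def conditional_observed_pmf(l, n, psi: float):
    """P(L = l | N = n) for conversion probability ``psi`` per position.

    Parameters
    ----------
    l : int or array-like
        Observed span, 0 <= l.
    n : int or array-like
        True tract length, n >= 1.
    psi : float
        Per-position allele conversion probability in [0, 1].

    Returns zero for ``l > n``. Vectorized over ``l`` and ``n``.
    """
    if not (0.0 <= psi <= 1.0):
        raise ValueError(f"psi must lie in [0, 1], got {psi}")
    l = np.asarray(l)
    n = np.asarray(n)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if np.any(l < 0):
        raise ValueError("l must be >= 0")
    l, n = np.broadcast_arrays(l, n)
    one_m = 1.0 - psi
    out = np.zeros(l.shape, dtype=float)
    m0 = l == 0
    out[m0] = one_m ** n[m0]
    m1 = (l == 1) & (n >= 1)
    out[m1] = n[m1] * psi * one_m ** (n[m1] - 1)
    m2 = (l >= 2) & (l <= n)
    out[m2] = (n[m2] - l[m2] + 1) * psi**2 * one_m ** (n[m2] - l[m2])
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Marginal distribution of L (log space)
# ---------------------------------------------------------------------------

def _log_marginal_geom(l, lam: float, psi):
    """log P(L = l) for geometric N; closed forms per observed-length case."""
    l = np.asarray(l, dtype=float)
    psi = np.asarray(psi, dtype=float)
    l, psi = np.broadcast_arrays(l, psi)
    # A = lam + psi - lam*psi = 1 - (1-lam)(1-psi)
    logA = np.log(lam + psi - lam * psi)
    log_lam = math.log(lam)
    log1m_lam = math.log1p(-lam)
    with np.errstate(divide="ignore"):
        log_psi = np.log(psi)
        log1m_psi = np.log1p(-psi)
    out = np.empty(l.shape, dtype=float)
    m0 = l == 0
    out[m0] = log_lam + log1m_psi[m0] - logA[m0]
    m1 = l == 1
    out[m1] = log_lam + log_psi[m1] - 2.0 * logA[m1]
    m2 = l >= 2
    out[m2] = log_lam + (l[m2] - 1.0) * log1m_lam + 2.0 * log_psi[m2] - 2.0 * logA[m2]
    return out


def _log_marginal_geom2(l, gamma: float, psi):
    """log P(L = l) for N a sum of two geometrics (rate gamma, support n >= 2).

    With r = 1-gamma, q = (1-psi) r, u = 1-q:
        P(L=0) = gamma^2 (1-psi)^2 / u^2
        P(L=1) = 2 psi gamma^2 (1-psi) / u^3
        P(L=l) = psi^2 gamma^2 r^(l-2) (1 + q + (l-2) u) / u^3,  l >= 2
    """
    l = np.asarray(l, dtype=float)
    psi = np.asarray(psi, dtype=float)
    l, psi = np.broadcast_arrays(l, psi)
    r = 1.0 - gamma
    q = (1.0 - psi) * r
    u = 1.0 - q  # = gamma + psi - gamma*psi
    logu = np.log(u)
    log_g = math.log(gamma)
    logr = math.log1p(-gamma)
    with np.errstate(divide="ignore"):
        log_psi = np.log(psi)
        log1m_psi = np.log1p(-psi)
    out = np.empty(l.shape, dtype=float)
    m0 = l == 0
    out[m0] = 2.0 * (log_g + log1m_psi[m0] - logu[m0])
    m1 = l == 1
    out[m1] = math.log(2.0) + log_psi[m1] + 2.0 * log_g + log1m_psi[m1] - 3.0 * logu[m1]
    m2 = l >= 2
    k = l[m2] - 2.0
    out[m2] = (
        2.0 * log_psi[m2]
        + 2.0 * log_g
        + k * logr
        + np.log1p(q[m2] + k * u[m2])
        - 3.0 * logu[m2]
    )
    return out


def log_marginal_pmf(model: TractLengthModel, l, psi):
    """log P(L = l) under ``model``; vectorized over ``l`` and ``psi``."""
    if isinstance(model, Geometric):
        return _log_marginal_geom(l, model.rate, psi)
    if isinstance(model, TwoGeometric):
        return _log_marginal_geom2(l, model.rate, psi)
    if isinstance(model, GeometricMixture):
        la = _log_marginal_geom(l, 1.0 / model.mean1, psi)
        lb = _log_marginal_geom(l, 1.0 / model.mean2, psi)
        return _logaddexp_weighted(la, lb, model.w1)
    raise TypeError(f"unknown model type {type(model)!r}")


def _logaddexp_weighted(la, lb, w1: float):
    """log(w1 e^la + (1-w1) e^lb), robust at w1 in {0, 1}."""
    if w1 <= 0.0:
        return np.asarray(lb, dtype=float)
    if w1 >= 1.0:
        return np.asarray(la, dtype=float)
    return np.logaddexp(math.log(w1) + la, math.log1p(-w1) + lb)


def marginal_pmf(model: TractLengthModel, l, psi):
    """P(L = l) under ``model`` (see :func:`log_marginal_pmf`)."""
    return np.exp(log_marginal_pmf(model, l, psi))


# ---------------------------------------------------------------------------
# Truncated distribution of L (log space, closed-form normalizers)
# ---------------------------------------------------------------------------

def _log_geom_tail_sum(lam: float, a: int, b: int) -> float:
    """log sum_{l=a}^{b} lam (1-lam)^(l-1) = log[(1-lam)^(a-1) - (1-lam)^b]."""
    c = math.log1p(-lam)
    # (1-lam)^(a-1) (1 - (1-lam)^(b-a+1))
    return (a - 1) * c + math.log(-math.expm1((b - a + 1) * c))


def _log_lin_geom_sum(logr: float, gamma: float, k0: int, k1: int) -> tuple[float, float]:
    """Return (log T0, log T1) where T0 = sum_{k=k0}^{k1} r^k, T1 = sum k r^k.

    r = exp(logr) = 1 - gamma. Uses expm1-based forms that stay accurate when
    gamma is tiny (r near 1).
    """
    # T0 = r^k0 (1 - r^(k1-k0+1)) / gamma
    logT0 = k0 * logr + math.log(-math.expm1((k1 - k0 + 1) * logr)) - math.log(gamma)

    def F(K: int) -> float:
        # F(K) = sum_{k=0}^{K} k r^k = r (1 - r^K (1 + K gamma)) / gamma^2
        if K <= 0:
            return 0.0
        inner = -math.expm1(K * logr + math.log1p(K * gamma))
        return math.exp(logr) * inner / gamma**2

    T1 = F(k1) - F(k0 - 1)
    logT1 = math.log(T1) if T1 > 0.0 else -math.inf
    return logT0, logT1


def _log_truncated_geom(l, lam: float, window: TruncationWindow):
    """psi-free truncated log-pmf for the geometric family (lmin >= 2).

    log P(L = l | lmin <= L <= lmax)
        = log lam + (l-1) log(1-lam) - log[(1-lam)^(lmin-1) - (1-lam)^lmax]
    """
    l = np.asarray(l, dtype=float)
    logZ = _log_geom_tail_sum(lam, window.lmin, window.lmax)
    return math.log(lam) + (l - 1.0) * math.log1p(-lam) - logZ


def _log_truncated_geom2(l, gamma: float, psi, window: TruncationWindow):
    l = np.asarray(l, dtype=float)
    psi = np.asarray(psi, dtype=float)
    l, psi = np.broadcast_arrays(l, psi)
    r = 1.0 - gamma
    logr = math.log1p(-gamma)
    q = (1.0 - psi) * r
    u = 1.0 - q
    k0, k1 = window.lmin - 2, window.lmax - 2
    logT0, logT1 = _log_lin_geom_sum(logr, gamma, k0, k1)
    # numerator (psi^2 gamma^2 / u^3 cancelled): r^(l-2) (1 + q + (l-2) u)
    k = l - 2.0
    log_num = k * logr + np.log1p(q + k * u)
    # normalizer: T0 (1 + q) + T1 u
    log_den = np.logaddexp(logT0 + np.log1p(q), logT1 + np.log(u))
    return log_num - log_den


def _log_truncated_mixture(l, model: GeometricMixture, psi, window: TruncationWindow):
    """Mixture truncated log-pmf; the common psi^2 factor cancels but psi
    remains through each component's A_i = lam_i + psi - lam_i psi."""
    l = np.asarray(l, dtype=float)
    psi = np.asarray(psi, dtype=float)
    l, psi = np.broadcast_arrays(l, psi)
    lam = (1.0 / model.mean1, 1.0 / model.mean2)
    w = (model.w1, 1.0 - model.w1)
    nums, dens = [], []
    for lam_i, w_i in zip(lam, w):
        if w_i <= 0.0:
            continue
        logA = np.log(lam_i + psi - lam_i * psi)
        # _log_geom_tail_sum already carries the lam_i factor of each term
        logS = _log_geom_tail_sum(lam_i, window.lmin, window.lmax)
        base = math.log(w_i) - 2.0 * logA
        nums.append(base + math.log(lam_i) + (l - 1.0) * math.log1p(-lam_i))
        dens.append(base + logS)
    if len(nums) == 1:
        return nums[0] - dens[0]
    return np.logaddexp(nums[0], nums[1]) - np.logaddexp(dens[0], dens[1])


def log_truncated_pmf(model: TractLengthModel, l, psi=None,
                      window: TruncationWindow = TruncationWindow()):
    """log P(L = l | lmin <= L <= lmax) under ``model``.

    For the geometric family (with lmin >= 2) the result does not involve
    ``psi`` at all. For the other families ``psi`` (scalar or per-observation
    array broadcast against ``l``) is required. Raises for ``l`` outside the
    window.
    """
    l_arr = np.asarray(l)
    if np.any(~window.contains(l_arr)):
        raise ValueError(f"observed lengths outside truncation window {window}")
    scalar = np.ndim(l) == 0 and (psi is None or np.ndim(psi) == 0)
    if window.lmin < 2:
        # General path: marginal ratio (needs psi even for the geometric
        # family since l = 1 carries a different psi power).
        if psi is None:
            raise ValueError("psi is required when lmin < 2")
        from scipy.special import logsumexp

        grid = np.arange(window.lmin, window.lmax + 1)
        psi_arr = np.atleast_1d(np.asarray(psi, dtype=float))
        lognum = log_marginal_pmf(model, l_arr, psi)
        logZ = logsumexp(
            log_marginal_pmf(model, grid[None, :], psi_arr[:, None]), axis=1
        )
        out = lognum - (logZ[0] if psi_arr.size == 1 else logZ)
    elif isinstance(model, Geometric):
        out = _log_truncated_geom(l_arr, model.rate, window)
    elif isinstance(model, TwoGeometric):
        if psi is None:
            raise ValueError("psi is required for the two-geometric family")
        out = _log_truncated_geom2(l_arr, model.rate, psi, window)
    elif isinstance(model, GeometricMixture):
        if psi is None:
            raise ValueError("psi is required for the mixture family")
        out = _log_truncated_mixture(l_arr, model, psi, window)
    else:
        raise TypeError(f"unknown model type {type(model)!r}")
    out = np.asarray(out, dtype=float)
    return float(out.reshape(-1)[0]) if scalar else out


def truncated_pmf(model: TractLengthModel, l, psi=None,
                  window: TruncationWindow = TruncationWindow()):
    """P(L = l | lmin <= L <= lmax); see :func:`log_truncated_pmf`."""
    return np.exp(log_truncated_pmf(model, l, psi, window))
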