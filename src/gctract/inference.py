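"""Truncated maximum-likelihood fitting, BIC selection and bootstrap CIs.

Each tract-length family is wrapped in a scikit-learn style estimator. The
training data ``X`` is either a 1-d array of observed tract lengths (bp) or a
2-d array with columns ``[length, psi_hat]``; all lengths must already lie in
the truncation window ``[lmin, lmax]``. Fitting maximizes

    sum_j log P(L_j = l_j | lmin <= L_j <= lmax, theta, psi_j = psi_hat_j)

over the rate parameter(s) with L-BFGS-B under box constraints. For the plain
geometric family the truncated likelihood does not involve ``psi_hat`` at all.
The mixture is fitted over a fixed grid of mixing weights with four rate-space
starting points per grid value, keeping the best joint likelihood.

Model comparison uses BIC = k ln(n) - 2 loglik with k = 1/1/3 parameters and
n the number of retained tracts. Percentile bootstrap confidence intervals
resample (length, psi) pairs jointly with replacement and refit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, DensityMixin, clone

from .models import (
    Geometric,
    GeometricMixture,
    TractLengthModel,
    TruncationWindow,
    TwoGeometric,
    log_truncated_pmf,
    model_mean,
)

__all__ = [
    "FitResult",
    "GeometricTractFitter",
    "TwoGeometricTractFitter",
    "MixtureTractFitter",
    "FITTER_CLASSES",
    "negative_log_likelihood",
    "fit_geometric",
    "fit_geom2",
    "fit_mixture",
    "fit_family",
    "select_model",
    "bootstrap_ci",
    "default_w1_grid",
]

_RATE_EPS = 1e-8
_FAMILY_ORDER = {"geometric": 0, "geom2": 1, "mixture": 2}


def default_w1_grid() -> np.ndarray:
    """Mixing-weight grid: 0.002..0.01 step 0.00025, then 0.05..0.5 step 0.05."""
    fine = np.round(np.arange(0.002, 0.01 + 1e-12, 0.00025), 8)
    coarse = np.round(np.arange(0.05, 0.5 + 1e-12, 0.05), 8)
    return np.concatenate([fine, coarse])


def negative_log_likelihood(model: TractLengthModel, lengths, psi=None,
                            window: TruncationWindow = TruncationWindow()) -> float:
    """Negative truncated log-likelihood of ``model`` for retained tracts.

    ``psi`` is ignored for the plain geometric family (whose truncated pmf is
    psi-free) and required otherwise. Lengths outside the window, or tracts
    producing a non-finite log-pmf, raise.
    """
    lengths = np.asarray(lengths)
    if lengths.size == 0:
        raise ValueError("retained tract set is empty")
    if isinstance(model, Geometric) and window.lmin >= 2:
        lp = log_truncated_pmf(model, lengths, None, window)
    else:
        if psi is None:
            raise ValueError("psi values are required for this model family")
        lp = log_truncated_pmf(model, lengths, psi, window)
    lp = np.atleast_1d(np.asarray(lp, dtype=float))
    bad = ~np.isfinite(lp)
    if np.any(bad):
        j = int(np.flatnonzero(bad)[0])
        raise FloatingPointError(
            f"non-finite log-pmf for tract index {j} (l={lengths.reshape(-1)[j]})"
        )
    return -float(lp.sum())


@dataclass
class FitResult:
    """Outcome of one truncated-ML fit."""

    family: str
    model: TractLengthModel
    loglik: float
    bic: float
    n_retained: int
    n_params: int
    window: TruncationWindow
    mean: float
    converged: bool = True
    at_bound: bool = False
    ci: dict[str, tuple[float, float]] | None = None
    bic_margins: dict[str, float] | None = None
    boot: dict | None = None

    def params(self) -> dict[str, float]:
        """Named parameter estimates, always including the overall mean."""
        m = self.model
        if isinstance(m, Geometric):
            return {"phi": 1.0 / m.rate, "mean": self.mean}
        if isinstance(m, TwoGeometric):
            return {"phi": 2.0 / m.rate, "mean": self.mean}
        return {"phi1": m.mean1, "phi2": m.mean2, "w1": m.w1, "mean": self.mean}

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "estimates": self.params(),
            "loglik": self.loglik,
            "bic": self.bic,
            "n_retained": self.n_retained,
            "n_params": self.n_params,
            "window": [self.window.lmin, self.window.lmax],
            "converged": self.converged,
            "at_bound": self.at_bound,
        }
        if self.ci is not None:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        if self.bic_margins is not None:
            d["bic_margins"] = self.bic_margins
        if self.boot is not None:
            d["bootstrap"] = {k: v for k, v in self.boot.items() if k != "draws"}
        return d


class _BaseTractFitter(DensityMixin, BaseEstimator):
    """Shared machinery for the truncated-ML tract-length fitters."""

    family: str = ""
    _needs_psi = True

    def __init__(self, lmin: int = 2, lmax: int = 1500, tol: float = 1e-8):
        self.lmin = lmin
        self.lmax = lmax
        self.tol = tol

    @property
    def _window(self) -> TruncationWindow:
        return TruncationWindow(self.lmin, self.lmax)

    def _validate(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            lengths, psi = X, None
        elif X.ndim == 2 and X.shape[1] == 2:
            lengths, psi = X[:, 0], X[:, 1]
        else:
            raise ValueError("X must be (n,) lengths or (n, 2) [length, psi]")
        if lengths.size == 0:
            raise ValueError("retained tract set is empty")
        window = self._window
        if np.any(~window.contains(lengths)):
            raise ValueError(
                f"all lengths must lie in [{window.lmin}, {window.lmax}]; "
                "filter before fitting"
            )
        if self._needs_psi:
            if psi is None:
                raise ValueError(
                    f"{type(self).__name__} requires per-tract psi values "
                    "(pass X with columns [length, psi])"
                )
            if np.any(psi <= 0.0) or np.any(psi > 1.0):
                raise ValueError("psi values must lie in (0, 1] for this family")
        return lengths, psi, window

    def _minimize(self, fun, x0, bounds):
        res = minimize(fun, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": self.tol, "gtol": 1e-10})
        return res

    def _finalize(self, model, nll, n, window):
        self.model_ = model
        self.loglik_ = -nll
        self.n_retained_ = int(n)
        self.n_params_ = model.n_params
        self.bic_ = model.n_params * math.log(n) - 2.0 * self.loglik_
        self.mean_ = model_mean(model)
        self.window_ = window
        if self.at_bound_:
            warnings.warn(
                f"{self.family} fit hit a rate bound; estimate may be degenerate",
                stacklevel=3,
            )

    def score(self, X, y=None) -> float:
        """Mean truncated log-likelihood per tract under the fitted model."""
        lengths, psi, window = self._validate(X)
        return -negative_log_likelihood(self.model_, lengths, psi, window) / lengths.size

    def result(self) -> FitResult:
        return FitResult(
            family=self.family,
            model=self.model_,
            loglik=self.loglik_,
            bic=self.bic_,
            n_retained=self.n_retained_,
            n_params=self.n_params_,
            window=self.window_,
            mean=self.mean_,
            converged=self.converged_,
            at_bound=self.at_bound_,
        )


class GeometricTractFitter(_BaseTractFitter):
    """Truncated-ML fit of a geometric tract-length distribution.

    The truncated likelihood is psi-free, so ``X`` may be a bare array of
    lengths; any psi column is accepted and ignored.
    """

    family = "geometric"
    _needs_psi = False

    def fit(self, X, y=None):
        lengths, _, window = self._validate(X)
        lam0 = float(np.clip(1.0 / lengths.mean(), _RATE_EPS * 10, 1 - _RATE_EPS * 10))
        bounds = [(_RATE_EPS, 1.0 - _RATE_EPS)]

        def nll(x):
            return negative_log_likelihood(Geometric(x[0]), lengths, None, window)

        res = self._minimize(nll, [lam0], bounds)
        if not res.success:
            raise RuntimeError(f"geometric fit failed to converge: {res.message}")
        lam = float(res.x[0])
        self.converged_ = bool(res.success)
        self.at_bound_ = lam <= bounds[0][0] * 2 or lam >= 1.0 - _RATE_EPS * 2
        self.rate_ = lam
        self._finalize(Geometric(lam), float(res.fun), lengths.size, window)
        return self


class TwoGeometricTractFitter(_BaseTractFitter):
    """Truncated-ML fit of a sum-of-two-geometrics tract-length distribution."""

    family = "geom2"

    def fit(self, X, y=None):
        lengths, psi, window = self._validate(X)
        gam0 = float(np.clip(2.0 / lengths.mean(), _RATE_EPS * 10, 1 - _RATE_EPS * 10))
        bounds = [(_RATE_EPS, 1.0 - _RATE_EPS)]

        def nll(x):
            return negative_log_likelihood(TwoGeometric(x[0]), lengths, psi, window)

        res = self._minimize(nll, [gam0], bounds)
        if not res.success:
            raise RuntimeError(f"geom2 fit failed to converge: {res.message}")
        gam = float(res.x[0])
        self.converged_ = bool(res.success)
        self.at_bound_ = gam <= bounds[0][0] * 2 or gam >= 1.0 - _RATE_EPS * 2
        self.rate_ = gam
        self._finalize(TwoGeometric(gam), float(res.fun), lengths.size, window)
        return self


def _mixture_nll_fast(lam1: float, lam2: float, w1: float, lm1: np.ndarray,
                      psi: np.ndarray, lmin: int, lmax: int) -> float:
    """Truncated mixture NLL without object construction or revalidation.

    Equivalent to ``negative_log_likelihood(GeometricMixture(...), ...)``
    (asserted in the tests); used inside the grid/multistart loop where the
    objective is evaluated tens of thousands of times.
    """
    terms_num, terms_den = [], []
    for lam, w in ((lam1, w1), (lam2, 1.0 - w1)):
        if w <= 0.0:
            continue
        c = math.log1p(-lam)
        logA2 = 2.0 * np.log(lam + psi - lam * psi)
        logS = (lmin - 1) * c + math.log(-math.expm1((lmax - lmin + 1) * c))
        logw = math.log(w)
        terms_num.append(logw + math.log(lam) + lm1 * c - logA2)
        terms_den.append(logw + logS - logA2)
    if len(terms_num) == 1:
        ll = terms_num[0].sum() - terms_den[0].sum()
    else:
        ll = (np.logaddexp(terms_num[0], terms_num[1]).sum()
              - np.logaddexp(terms_den[0], terms_den[1]).sum())
    return -float(ll)


class MixtureTractFitter(_BaseTractFitter):
    """Truncated-ML fit of a two-component geometric mixture.

    For each mixing weight in ``w1_grid`` the two component rates are
    optimized with L-BFGS-B from each starting pair in ``rate_starts``
    (rate scale); the best joint likelihood over grid points and starts wins,
    with likelihood ties broken toward the smaller grid weight. Components are
    reported sorted by mean descending, ``w1`` being the long component's
    weight.
    """

    family = "mixture"

    def __init__(self, lmin: int = 2, lmax: int = 1500, tol: float = 1e-8,
                 w1_grid=None, rate_starts=((0.0005, 0.0005), (0.0005, 0.1),
                                            (0.1, 0.0005), (0.1, 0.1))):
        super().__init__(lmin=lmin, lmax=lmax, tol=tol)
        self.w1_grid = w1_grid
        self.rate_starts = rate_starts

    def fit(self, X, y=None):
        lengths, psi, window = self._validate(X)
        grid = default_w1_grid() if self.w1_grid is None else np.asarray(self.w1_grid, float)
        bounds = [(_RATE_EPS, 1.0 - _RATE_EPS)] * 2
        best = None  # (nll, w1, lam1, lam2)
        n_fail = 0
        lm1 = lengths - 1.0
        for w1 in grid:
            def nll(x, w1=float(w1)):
                return _mixture_nll_fast(x[0], x[1], w1, lm1, psi,
                                         window.lmin, window.lmax)

            for start in self.rate_starts:
                res = self._minimize(nll, list(start), bounds)
                if not res.success:
                    n_fail += 1
                    continue
                cand = (float(res.fun), float(w1), float(res.x[0]), float(res.x[1]))
                if best is None or cand[0] < best[0] - 0.0:
                    best = cand
        if best is None:
            raise RuntimeError("all mixture optimizations failed")
        nll_opt, w1, lam1, lam2 = best
        # label components: component 1 = long component
        phi_a, phi_b = 1.0 / lam1, 1.0 / lam2
        if phi_a >= phi_b:
            model = GeometricMixture(phi_a, phi_b, w1)
        else:
            model = GeometricMixture(phi_b, phi_a, 1.0 - w1)
        self.converged_ = True
        self.n_failed_starts_ = n_fail
        self.at_bound_ = any(
            r <= _RATE_EPS * 2 or r >= 1.0 - _RATE_EPS * 2 for r in (lam1, lam2)
        )
        self.weights_ = np.array([model.w1, 1.0 - model.w1])
        self.means_ = np.array([model.mean1, model.mean2])
        self._finalize(model, nll_opt, lengths.size, window)
        return self


FITTER_CLASSES = {
    "geometric": GeometricTractFitter,
    "geom2": TwoGeometricTractFitter,
    "mixture": MixtureTractFitter,
}


def _pack(lengths, psi):
    lengths = np.asarray(lengths, dtype=float)
    if psi is None:
        return lengths
    return np.column_stack([lengths, np.asarray(psi, dtype=float)])


def fit_family(family: str, lengths, psi=None,
               window: TruncationWindow = TruncationWindow(), **kwargs) -> FitResult:
    """Fit one family by name ('geometric', 'geom2' or 'mixture')."""
    cls = FITTER_CLASSES[family]
    est = cls(lmin=window.lmin, lmax=window.lmax, **kwargs)
    est.fit(_pack(lengths, psi))
    return est.result()


def fit_geometric(lengths, psi=None, window=TruncationWindow(), **kw) -> FitResult:
    return fit_family("geometric", lengths, psi, window, **kw)


def fit_geom2(lengths, psi, window=TruncationWindow(), **kw) -> FitResult:
    return fit_family("geom2", lengths, psi, window, **kw)


def fit_mixture(lengths, psi, window=TruncationWindow(), **kw) -> FitResult:
    return fit_family("mixture", lengths, psi, window, **kw)


def select_model(fits: Sequence[FitResult]) -> FitResult:
    """Return the fit with the smallest BIC, recording pairwise margins.

    Exact BIC ties fall back to the simplest-first order geometric < geom2 <
    mixture. All candidates must be fits of the same retained data.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no candidate fits")
    ns = {f.n_retained for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits are on different retained sets: n = {sorted(ns)}")
    best = min(fits, key=lambda f: (f.bic, _FAMILY_ORDER.get(f.family, 99)))
    best.bic_margins = {
        f.family: f.bic - best.bic for f in fits if f is not best
    }
    return best


def bootstrap_ci(lengths, psi, family: str = "geometric", n_boot: int = 500,
                 quantiles: tuple[float, float] = (0.025, 0.975),
                 seed: int | None = None,
                 window: TruncationWindow = TruncationWindow(),
                 max_fail_frac: float = 0.05, **fit_kwargs) -> dict:
    """Percentile bootstrap intervals for the parameters of one family.

    Resamples (length, psi) pairs jointly with replacement, refits, and takes
    empirical quantiles of each parameter (including the overall mean). The
    root ``seed`` spawns one child stream per resample, so results are fully
    reproducible. More than ``max_fail_frac`` failed refits is an error.

    Returns ``{"ci": {param: (lo, hi)}, "draws": DataFrame-like dict,
    "n_boot": ..., "seed": ...}``.
    """
    lengths = np.asarray(lengths)
    n = lengths.size
    if n == 0:
        raise ValueError("retained tract set is empty")
    psi_arr = None if psi is None else np.asarray(psi, dtype=float)
    template = FITTER_CLASSES[family](lmin=window.lmin, lmax=window.lmax, **fit_kwargs)
    streams = np.random.SeedSequence(seed).spawn(n_boot)
    draws: dict[str, list[float]] = {}
    n_fail = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        idx = rng.integers(0, n, size=n)
        lb = lengths[idx]
        pb = None if psi_arr is None else psi_arr[idx]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = clone(template).fit(_pack(lb, pb))
            params = est.result().params()
        except Exception:
            n_fail += 1
            continue
        for k, v in params.items():
            draws.setdefault(k, []).append(v)
    if n_fail > max_fail_frac * n_boot:
        raise RuntimeError(
            f"{n_fail}/{n_boot} bootstrap refits failed (> {max_fail_frac:.0%})"
        )
    ci = {
        k: tuple(np.quantile(np.asarray(v), quantiles)) for k, v in draws.items()
    }
    return {"ci": ci, "draws": draws, "n_boot": n_boot, "n_failed": n_fail,
            "seed": seed, "quantiles": quantiles}
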