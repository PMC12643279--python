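"""Truncated-ML fitting, BIC selection and bootstrap behaviour."""

import warnings

import numpy as np
import pytest

from gctract.inference import (
    FitResult,
    GeometricTractFitter,
    MixtureTractFitter,
    bootstrap_ci,
    default_w1_grid,
    fit_geom2,
    fit_geometric,
    fit_mixture,
    negative_log_likelihood,
    select_model,
)
from gctract.models import (
    Geometric,
    GeometricMixture,
    TruncationWindow,
    TwoGeometric,
    log_truncated_pmf,
)

WINDOW = TruncationWindow()


def sample_truncated_geometric(mean, n, rng):
    """Rejection-sample observed lengths from the psi-free truncated geometric."""
    out = []
    while len(out) < n:
        draw = rng.geometric(1.0 / mean, size=4 * n)
        out.extend(draw[(draw >= WINDOW.lmin) & (draw <= WINDOW.lmax)][: n - len(out)])
    return np.array(out)


class TestNegativeLogLikelihood:
    def test_single_tract_closed_form(self):
        lam, l = 1 / 250, 40
        expected = -np.log(
            lam * (1 - lam) ** (l - 1) / ((1 - lam) - (1 - lam) ** 1500)
        )
        got = negative_log_likelihood(Geometric(lam), np.array([l]))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_additivity_under_duplication(self, rng):
        lengths = sample_truncated_geometric(100, 200, rng)
        psi = np.full(lengths.size, 1e-3)
        m = TwoGeometric(2 / 120)
        single = negative_log_likelihood(m, lengths, psi)
        double = negative_log_likelihood(
            m, np.concatenate([lengths, lengths]), np.concatenate([psi, psi])
        )
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_permutation_invariance(self, rng):
        lengths = sample_truncated_geometric(60, 300, rng)
        psi = rng.uniform(1e-4, 1e-2, lengths.size)
        m = GeometricMixture(500.0, 30.0, 0.01)
        perm = rng.permutation(lengths.size)
        assert negative_log_likelihood(m, lengths, psi) == pytest.approx(
            negative_log_likelihood(m, lengths[perm], psi[perm]), rel=1e-12
        )

    def test_matches_per_tract_scalar_loop(self, rng):
        lengths = sample_truncated_geometric(80, 100, rng)
        psi = rng.uniform(1e-4, 5e-3, lengths.size)
        m = GeometricMixture(724.7, 16.9, 0.00525)
        loop = -sum(
            log_truncated_pmf(m, int(l), float(p), WINDOW)
            for l, p in zip(lengths, psi)
        )
        vec = negative_log_likelihood(m, lengths, psi)
        assert vec == pytest.approx(loop, rel=1e-9)

    def test_requires_window_filtering(self):
        with pytest.raises(ValueError):
            negative_log_likelihood(Geometric(0.01), np.array([1, 10]))


class TestGeometricFit:
    def test_parameter_recovery(self, rng):
        lengths = sample_truncated_geometric(300, 2000, rng)
        fr = fit_geometric(lengths)
        # MC SD of the mean estimate at n=2000 is roughly 7 bp here
        assert fr.mean == pytest.approx(300, abs=21)
        assert fr.n_params == 1
        assert fr.bic == pytest.approx(np.log(2000) - 2 * fr.loglik)

    def test_fit_ignores_psi_values(self, rng):
        lengths = sample_truncated_geometric(150, 500, rng)
        a = fit_geometric(lengths, np.full(lengths.size, 1e-3))
        b = fit_geometric(lengths, np.full(lengths.size, 0.4))
        assert a.mean == b.mean

    def test_permutation_invariant_estimates(self, rng):
        lengths = sample_truncated_geometric(90, 400, rng)
        a = fit_geometric(lengths)
        b = fit_geometric(rng.permutation(lengths))
        # identical up to floating-point summation order in the objective
        assert a.mean == pytest.approx(b.mean, rel=1e-6)

    def test_single_tract_at_window_edge_flags_boundary(self):
        with pytest.warns(UserWarning, match="bound"):
            fr = fit_geometric(np.array([2]))
        assert fr.at_bound

    def test_sklearn_interface(self, rng):
        lengths = sample_truncated_geometric(100, 300, rng)
        est = GeometricTractFitter()
        assert est.get_params()["lmax"] == 1500
        est.fit(lengths.astype(float))
        assert est.mean_ > 0 and est.bic_ > 0
        assert est.score(lengths.astype(float)) == pytest.approx(
            est.loglik_ / lengths.size
        )


class TestGeom2AndMixtureFit:
    def test_geom2_requires_positive_psi(self, rng):
        lengths = sample_truncated_geometric(100, 50, rng)
        with pytest.raises(ValueError, match="psi"):
            fit_geom2(lengths, np.zeros(lengths.size))

    def test_mixture_likelihood_dominates_geometric_on_any_data(self, rng):
        # the mixture nests the geometric (equal components), so its
        # maximized likelihood cannot be lower up to optimizer tolerance
        lengths = sample_truncated_geometric(120, 300, rng)
        psi = np.full(lengths.size, 1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frg = fit_geometric(lengths)
            frm = fit_mixture(lengths, psi, w1_grid=[0.002, 0.1, 0.5])
        assert frm.loglik >= frg.loglik - 1e-6

    def test_symmetric_two_rate_recovery_with_degenerate_grid(self, rng):
        # w1 fixed at 0.5 with equal-component data reduces to a symmetric
        # two-rate fit; both components should land near the shared truth
        lengths = sample_truncated_geometric(200, 2000, rng)
        psi = np.full(lengths.size, 1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fr = fit_mixture(lengths, psi, w1_grid=[0.5])
        assert fr.model.w1 == pytest.approx(0.5)
        assert fr.mean == pytest.approx(200, rel=0.2)

    def test_mixture_component_labelling(self, rng):
        lengths = sample_truncated_geometric(150, 200, rng)
        psi = np.full(lengths.size, 1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fr = fit_mixture(lengths, psi, w1_grid=[0.05, 0.2])
        assert fr.model.mean1 >= fr.model.mean2  # component 1 = long component

    def test_fast_objective_matches_general_nll(self, rng):
        from gctract.inference import _mixture_nll_fast

        lengths = sample_truncated_geometric(100, 500, rng).astype(float)
        psi = rng.uniform(1e-4, 2e-3, lengths.size)
        for lam1, lam2, w1 in [(1 / 725, 1 / 17.5, 0.005), (0.0005, 0.1, 0.2),
                               (0.3, 0.001, 0.5), (0.01, 0.01, 1.0)]:
            fast = _mixture_nll_fast(lam1, lam2, w1, lengths - 1.0, psi, 2, 1500)
            general = negative_log_likelihood(
                GeometricMixture(1 / lam1, 1 / lam2, w1), lengths, psi, WINDOW
            )
            assert fast == pytest.approx(general, rel=1e-10)

    def test_default_w1_grid_matches_benchmark_design(self):
        grid = default_w1_grid()
        assert grid[0] == pytest.approx(0.002)
        assert grid[-1] == pytest.approx(0.5)
        fine = grid[grid <= 0.011]
        assert np.allclose(np.diff(fine), 0.00025)
        coarse = grid[grid >= 0.05]
        assert np.allclose(np.diff(coarse), 0.05)
        assert grid.size == 33 + 10


class TestSelectModel:
    def _fr(self, family, bic, n=100):
        model = {
            "geometric": Geometric(0.01),
            "geom2": TwoGeometric(0.02),
            "mixture": GeometricMixture(700.0, 20.0, 0.01),
        }[family]
        loglik = (model.n_params * np.log(n) - bic) / 2
        return FitResult(family=family, model=model, loglik=loglik, bic=bic,
                         n_retained=n, n_params=model.n_params, window=WINDOW,
                         mean=model.mean)

    def test_benchmark_bic_triple_selects_mixture(self):
        fits = [
            self._fr("geometric", 12_201_928, n=876_584),
            self._fr("geom2", 12_268_165, n=876_584),
            self._fr("mixture", 11_860_358, n=876_584),
        ]
        best = select_model(fits)
        assert best.family == "mixture"
        assert best.bic_margins["geometric"] == pytest.approx(341_570)

    def test_tie_break_prefers_simplest_family(self):
        fits = [self._fr("mixture", 1000.0), self._fr("geometric", 1000.0),
                self._fr("geom2", 1000.0)]
        assert select_model(fits).family == "geometric"

    def test_single_candidate_returned_unchanged(self):
        fr = self._fr("geometric", 123.0)
        assert select_model([fr]) is fr

    def test_mismatched_retained_counts_raise(self):
        with pytest.raises(ValueError):
            select_model([self._fr("geometric", 1.0, n=10),
                          self._fr("geom2", 2.0, n=20)])


class TestBootstrap:
    def test_seed_determinism(self, rng):
        lengths = sample_truncated_geometric(100, 60, rng)
        a = bootstrap_ci(lengths, None, "geometric", n_boot=5, seed=42)
        b = bootstrap_ci(lengths, None, "geometric", n_boot=5, seed=42)
        assert a["ci"] == b["ci"]
        c = bootstrap_ci(lengths, None, "geometric", n_boot=5, seed=43)
        assert a["ci"] != c["ci"]

    def test_identical_tracts_give_zero_width_interval(self):
        lengths = np.full(30, 7)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            boot = bootstrap_ci(lengths, None, "geometric", n_boot=10, seed=0)
        lo, hi = boot["ci"]["mean"]
        assert lo == pytest.approx(hi)

    def test_interval_brackets_truth_for_well_specified_data(self, rng):
        lengths = sample_truncated_geometric(100, 500, rng)
        boot = bootstrap_ci(lengths, None, "geometric", n_boot=60, seed=9)
        lo, hi = boot["ci"]["mean"]
        assert lo < 100 < hi
        assert lo <= fit_geometric(lengths).mean <= hi
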