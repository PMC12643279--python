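"""Synthetic haplotype panels and gene-conversion tract overlay.

The panel emulates diploid individuals carrying heterozygous common-variant
(MAF >= 5%) sites at biobank-like density over a single region: site
positions follow a homogeneous Poisson process (default one common site per
450 bp over 10 Mb), per-site minor allele frequencies follow a truncated
neutral spectrum (density proportional to 1/x on [0.05, 0.5]), and each
individual is heterozygous at a site independently with Hardy-Weinberg
probability 2p(1-p). There is no linkage disequilibrium between sites: the
likelihood model conditions only on per-position heterozygosity, which is
exactly what the panel reproduces.

Tract overlay draws true tract lengths from a generating distribution
(geometric, sums of two or three geometrics, discrete uniform, or a
two-component geometric mixture), places each tract uniformly on the region
for an individual sampled with replacement, and records the observed length
as the inclusive span of the outermost heterozygous sites inside the tract
(0 with no such site, 1 with exactly one). The robustness experiment repeats
overlay/subsample/fit cycles and aggregates bias, spread, bootstrap-CI
coverage and BIC model selection counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import (
    FITTER_CLASSES,
    FitResult,
    bootstrap_ci,
    fit_family,
    select_model,
)
from .models import TruncationWindow
from .psi import FrequencyTrack, ObservedTract, attach_psi

__all__ = [
    "GeneratorSpec",
    "HaplotypePanel",
    "standard_generators",
    "OverlayResult",
    "RobustnessResult",
    "simulate_panel",
    "draw_tract_length",
    "draw_tract_lengths",
    "overlay_tracts",
    "run_robustness_experiment",
]

_SIM_CHROM = "sim1"


@dataclass(frozen=True)
class GeneratorSpec:
    """A true tract-length generating distribution.

    family is one of 'geom', 'geom2', 'geom3', 'uniform', 'mixture'.
    For the geometric families ``phi`` is the overall mean (each of the k
    summed geometrics has mean phi/k, so geom2/geom3 have minimum support
    2/3). 'uniform' is the discrete uniform on {1, ..., support}. 'mixture'
    draws from component 1 (mean phi1) with probability w1, else component 2.
    """

    family: str
    phi: float | None = None
    support: int | None = None
    phi1: float | None = None
    phi2: float | None = None
    w1: float | None = None

    def __post_init__(self) -> None:
        fams = {"geom", "geom2", "geom3", "uniform", "mixture"}
        if self.family not in fams:
            raise ValueError(f"family must be one of {sorted(fams)}")
        if self.family in {"geom", "geom2", "geom3"} and not self.phi:
            raise ValueError(f"{self.family} requires phi")
        if self.family == "uniform" and not self.support:
            raise ValueError("uniform requires support")
        if self.family == "mixture" and None in (self.phi1, self.phi2, self.w1):
            raise ValueError("mixture requires phi1, phi2 and w1")

    @property
    def true_mean(self) -> float:
        if self.family in {"geom", "geom2", "geom3"}:
            return float(self.phi)
        if self.family == "uniform":
            return (self.support + 1) / 2.0
        return self.w1 * self.phi1 + (1.0 - self.w1) * self.phi2

    def label(self) -> str:
        if self.family == "uniform":
            return f"uniform(1..{self.support})"
        if self.family == "mixture":
            return f"mixture({self.phi1}, {self.phi2}, w1={self.w1})"
        return f"{self.family}(mean {self.phi})"


def standard_generators() -> dict[str, GeneratorSpec]:
    """The ten benchmark generating distributions (five families, two means).

    Each reproduces its nominal mean exactly: geometric / sum-of-two /
    sum-of-three geometrics at means 21 and 100 bp, discrete uniforms on
    1..41 and 1..199, and two-component mixtures (725, 17.5, w1=0.005) and
    (700, 68.4, w1=0.05).
    """
    return {
        "geom_21": GeneratorSpec("geom", phi=21),
        "geom_100": GeneratorSpec("geom", phi=100),
        "geom2_21": GeneratorSpec("geom2", phi=21),
        "geom2_100": GeneratorSpec("geom2", phi=100),
        "geom3_21": GeneratorSpec("geom3", phi=21),
        "geom3_100": GeneratorSpec("geom3", phi=100),
        "uniform_21": GeneratorSpec("uniform", support=41),
        "uniform_100": GeneratorSpec("uniform", support=199),
        "mixture_21": GeneratorSpec("mixture", phi1=725, phi2=17.5, w1=0.005),
        "mixture_100": GeneratorSpec("mixture", phi1=700, phi2=68.4, w1=0.05),
    }


def draw_tract_lengths(spec: GeneratorSpec, rng: np.random.Generator,
                       size: int) -> np.ndarray:
    """Vectorized draw of ``size`` true tract lengths."""
    if spec.family == "geom":
        return rng.geometric(1.0 / spec.phi, size)
    if spec.family in {"geom2", "geom3"}:
        k = 2 if spec.family == "geom2" else 3
        return rng.geometric(k / spec.phi, size=(k, size)).sum(axis=0)
    if spec.family == "uniform":
        return rng.integers(1, spec.support + 1, size)
    comp1 = rng.random(size) < spec.w1
    draws = np.where(
        comp1,
        rng.geometric(1.0 / spec.phi1, size),
        rng.geometric(1.0 / spec.phi2, size),
    )
    return draws


def draw_tract_length(spec: GeneratorSpec, rng: np.random.Generator) -> int:
    """Draw a single true tract length (bp)."""
    return int(draw_tract_lengths(spec, rng, 1)[0])


@dataclass
class HaplotypePanel:
    """Synthetic diploid panel: common-variant sites and per-individual hets.

    ``het_positions``/``het_indptr`` store each individual's sorted
    heterozygous-site positions in CSR layout.
    """

    region_length: int
    n_individuals: int
    site_positions: np.ndarray
    site_maf: np.ndarray
    het_positions: np.ndarray
    het_indptr: np.ndarray
    _global_keys: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self._global_keys is None:
            stride = self.region_length + 2
            owner = np.repeat(
                np.arange(self.n_individuals, dtype=np.int64),
                np.diff(self.het_indptr),
            )
            self._global_keys = owner * stride + self.het_positions

    def het_sites(self, i: int) -> np.ndarray:
        """Sorted heterozygous-site positions of individual ``i``."""
        return self.het_positions[self.het_indptr[i]:self.het_indptr[i + 1]]

    def frequency_track(self, chromosome: str = _SIM_CHROM) -> FrequencyTrack:
        return FrequencyTrack(
            chromosome=chromosome,
            positions=self.site_positions,
            maf=self.site_maf,
            chrom_length=self.region_length,
        )


def simulate_panel(region_length: int = 10_000_000, n_individuals: int = 1000,
                   site_density: float = 1.0 / 450.0, maf_min: float = 0.05,
                   maf_max: float = 0.5, seed=None) -> HaplotypePanel:
    """Build a synthetic panel; fully reproducible given ``seed``.

    ``site_density`` is the expected number of MAF >= ``maf_min`` sites per
    bp; MAFs are drawn from the 1/x spectrum truncated to
    [``maf_min``, ``maf_max``].
    """
    if not (0.0 < site_density < 1.0):
        raise ValueError("site_density must lie in (0, 1)")
    if not (0.0 < maf_min <= maf_max <= 0.5):
        raise ValueError("require 0 < maf_min <= maf_max <= 0.5")
    rng = np.random.default_rng(seed)
    n_sites = rng.poisson(region_length * site_density)
    positions = np.unique(rng.integers(1, region_length + 1, n_sites))
    # inverse-CDF of density ∝ 1/x on [maf_min, maf_max]
    maf = maf_min * (maf_max / maf_min) ** rng.random(positions.size)
    het_prob = 2.0 * maf * (1.0 - maf)
    chunks = []
    counts = np.empty(n_individuals, dtype=np.int64)
    block = 200
    for start in range(0, n_individuals, block):
        stop = min(start + block, n_individuals)
        hit = rng.random((stop - start, positions.size)) < het_prob
        for k in range(stop - start):
            sel = positions[hit[k]]
            chunks.append(sel)
            counts[start + k] = sel.size
    het_positions = np.concatenate(chunks) if chunks else np.empty(0, np.int64)
    indptr = np.concatenate([[0], np.cumsum(counts)])
    return HaplotypePanel(
        region_length=region_length,
        n_individuals=n_individuals,
        site_positions=positions,
        site_maf=maf,
        het_positions=het_positions.astype(np.int64),
        het_indptr=indptr,
    )


@dataclass
class OverlayResult:
    """Observed outcomes for a batch of overlaid tracts.

    ``a``/``b`` are the outermost heterozygous positions (-1 when the tract
    covered no heterozygous site); ``lengths`` is 0 / 1 / b - a + 1.
    """

    lengths: np.ndarray
    a: np.ndarray
    b: np.ndarray
    true_lengths: np.ndarray
    individual: np.ndarray


def overlay_tracts(panel: HaplotypePanel, spec: GeneratorSpec,
                   individuals_sampled: int = 10_000,
                   tracts_per_individual: int = 100,
                   seed=None) -> OverlayResult:
    """Overlay random tracts on the panel and record observed spans.

    Individuals are sampled with replacement; each receives
    ``tracts_per_individual`` tracts with uniform start positions and lengths
    drawn from ``spec``. Tracts overhanging the region end are clipped at the
    boundary.
    """
    rng = np.random.default_rng(seed)
    ids = rng.integers(0, panel.n_individuals, individuals_sampled)
    indiv = np.repeat(ids, tracts_per_individual)
    m = indiv.size
    starts = rng.integers(1, panel.region_length + 1, m)
    true_n = draw_tract_lengths(spec, rng, m)
    ends = np.minimum(starts + true_n - 1, panel.region_length)
    stride = panel.region_length + 2
    base = indiv.astype(np.int64) * stride
    keys = panel._global_keys
    lo = np.searchsorted(keys, base + starts, side="left")
    hi = np.searchsorted(keys, base + ends, side="right")
    count = hi - lo
    a = np.full(m, -1, dtype=np.int64)
    b = np.full(m, -1, dtype=np.int64)
    hit = count >= 1
    a[hit] = keys[lo[hit]] - base[hit]
    b[hit] = keys[hi[hit] - 1] - base[hit]
    lengths = np.where(hit, b - a + 1, 0).astype(np.int64)
    return OverlayResult(lengths=lengths, a=a, b=b, true_lengths=true_n,
                         individual=indiv)


@dataclass
class RobustnessResult:
    """Aggregated robustness-experiment output (bias/SD/coverage, selection)."""

    spec: GeneratorSpec
    true_mean: float
    n_replicates: int
    n_retained: int
    replicates: pd.DataFrame
    summary: pd.DataFrame
    selection_counts: dict[str, int]
    seed: object = None


def _replicate_sample(panel: HaplotypePanel, spec: GeneratorSpec,
                      window: TruncationWindow, n_retained: int,
                      rng: np.random.Generator, individuals_sampled: int,
                      tracts_per_individual: int, flank: int, maf_min: float):
    ov = overlay_tracts(panel, spec, individuals_sampled,
                        tracts_per_individual, seed=rng)
    keep = np.flatnonzero(window.contains(ov.lengths))
    if keep.size < n_retained:
        raise RuntimeError(
            f"only {keep.size} observed lengths in "
            f"[{window.lmin}, {window.lmax}] but {n_retained} requested; "
            "use a larger panel or more tracts per individual"
        )
    sub = rng.choice(keep, size=n_retained, replace=False)
    tracts = [
        ObservedTract(_SIM_CHROM, int(ov.a[i]), int(ov.b[i])) for i in sub
    ]
    tracts = attach_psi(tracts, {_SIM_CHROM: panel.frequency_track()},
                        flank=flank, maf_min=maf_min)
    lengths = np.array([t.length for t in tracts])
    psi = np.array([t.psi_hat for t in tracts])
    return lengths, psi


def run_robustness_experiment(spec: GeneratorSpec, n_replicates: int = 100,
                              n_retained: int = 50,
                              fit_families: Sequence[str] = ("geometric", "geom2", "mixture"),
                              bootstrap_families: Sequence[str] = (),
                              n_boot: int = 100,
                              seed=None,
                              panel: HaplotypePanel | None = None,
                              window: TruncationWindow = TruncationWindow(),
                              individuals_sampled: int = 10_000,
                              tracts_per_individual: int = 100,
                              flank: int = 5000, maf_min: float = 0.05,
                              mixture_kwargs: dict | None = None,
                              ) -> RobustnessResult:
    """Replicate overlay/subsample/fit cycles and aggregate the results.

    Per replicate: overlay tracts on the panel, subsample ``n_retained``
    observed lengths inside the truncation window, attach psi-hat from the
    panel's frequency track, fit the requested families, record the BIC
    winner, and (for ``bootstrap_families``) a percentile-bootstrap CI for
    the overall mean. The summary table reports per-family empirical bias,
    SD and CI coverage of the true mean, plus a 'bic_selected' row when more
    than one family is fitted.
    """
    true_mean = spec.true_mean
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    panel_ss, *rep_ss = root.spawn(n_replicates + 1)
    if panel is None:
        panel = simulate_panel(seed=panel_ss)
    rows = []
    import warnings as _warnings

    for rep, ss in enumerate(rep_ss):
        rng = np.random.default_rng(ss)
        lengths, psi = _replicate_sample(
            panel, spec, window, n_retained, rng, individuals_sampled,
            tracts_per_individual, flank, maf_min,
        )
        fits: dict[str, FitResult] = {}
        row: dict = {"replicate": rep}
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            for fam in fit_families:
                kw = dict(mixture_kwargs or {}) if fam == "mixture" else {}
                fr = fit_family(fam, lengths, psi, window, **kw)
                fits[fam] = fr
                row[f"{fam}_mean"] = fr.mean
                row[f"{fam}_bic"] = fr.bic
            if len(fits) > 1:
                winner = select_model(list(fits.values()))
                row["bic_selected"] = winner.family
                row["bic_selected_mean"] = winner.mean
            for fam in bootstrap_families:
                boot = bootstrap_ci(
                    lengths, psi, family=fam, n_boot=n_boot,
                    seed=int(rng.integers(0, 2**31 - 1)), window=window,
                )
                lo, hi = boot["ci"]["mean"]
                row[f"{fam}_ci_lo"], row[f"{fam}_ci_hi"] = lo, hi
                row[f"{fam}_covered"] = bool(lo <= true_mean <= hi)
        rows.append(row)
    reps = pd.DataFrame(rows)
    summary_rows = []
    for fam in fit_families:
        est = reps[f"{fam}_mean"]
        entry = {
            "family": fam,
            "bias": est.mean() - true_mean,
            "sd": est.std(ddof=1),
        }
        if f"{fam}_covered" in reps:
            entry["coverage"] = reps[f"{fam}_covered"].mean()
        summary_rows.append(entry)
    if "bic_selected_mean" in reps:
        est = reps["bic_selected_mean"]
        summary_rows.append({
            "family": "bic_selected",
            "bias": est.mean() - true_mean,
            "sd": est.std(ddof=1),
        })
    selection = (
        reps["bic_selected"].value_counts().to_dict()
        if "bic_selected" in reps else {}
    )
    return RobustnessResult(
        spec=spec, true_mean=true_mean, n_replicates=n_replicates,
        n_retained=n_retained, replicates=reps,
        summary=pd.DataFrame(summary_rows), selection_counts=selection,
        seed=seed,
    )
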