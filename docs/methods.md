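# Methods

## Problem and model

Non-crossover gene conversion copies a short tract of sequence between
homologous chromosomes. Population-scale detection methods recover, for each
event, only the positions where an allele was actually converted, so the
quantity observed per tract is the inclusive span `L` between the outermost
converted positions — not the true tract length `N`. `gctract` infers the
distribution of `N` from a collection of observed spans.

The true length is modeled by one of three families:

* **geometric** on `{1, 2, ...}` with rate `λ = 1/φ` (a tract that extends
  bp by bp with constant stopping probability);
* **sum of two i.i.d. geometrics** on `{2, 3, ...}` with per-side rate
  `γ = 2/φ` (outward extension from an initiation point);
* **two-component geometric mixture** with component means `φ1 ≥ φ2` and
  long-component weight `w1`, accommodating a heavy upper tail.

Conditional on `N = n` and a per-bp allele conversion probability `ψ`,

    P(L = 0 | n) = (1 − ψ)^n
    P(L = 1 | n) = n ψ (1 − ψ)^{n−1}
    P(L = l | n) = (n − l + 1) ψ² (1 − ψ)^{n−l},   2 ≤ l ≤ n.

Marginalizing over each family yields closed forms. For the geometric
family, with `A = λ + ψ − λψ`:

    P(L = 0) = λ(1 − ψ)/A,   P(L = 1) = λψ/A²,
    P(L = l) = λ(1 − λ)^{l−1} ψ² / A²   (l ≥ 2).

For the sum of two geometrics (`P(N = n) = (n − 1)γ²(1 − γ)^{n−2}`), writing
`r = 1 − γ`, `q = (1 − ψ)r` and `u = 1 − q`, we derived

    P(L = 0) = γ²(1 − ψ)²/u²,   P(L = 1) = 2ψγ²(1 − ψ)/u³,
    P(L = l) = ψ²γ² r^{l−2} (1 + q + (l − 2)u) / u³   (l ≥ 2),

validated in the test suite against a brute-force summation oracle
(`Σ_n P(L = l | N = n) P(N = n)` with the tail extended until it is below
1e-12 of total mass). The mixture marginal is the weighted sum of two
geometric marginals.

## Truncation

Detection constraints motivate retaining only spans in a window
`[lmin, lmax]` (default `[2, 1500]`): spans of 1 bp are distorted by linkage
disequilibrium between nearby variants, and spans above 1.5 kb fall outside
detection windows. The likelihood conditions on `lmin ≤ L ≤ lmax`. For the
geometric family this conditioning cancels `ψ` entirely:

    P(L = l | 2 ≤ L ≤ 1500) = λ(1 − λ)^{l−1} / [(1 − λ) − (1 − λ)^{1500}],

so geometric fits need no conversion-probability estimates at all. For the
other two families the common `ψ²` factor cancels between numerator and
normalizer but `ψ` survives inside `q` and `A`, so per-tract estimates
`ψ̂_j` enter the likelihood.

## Estimating ψ per tract

`ψ̂_j` is the average Hardy–Weinberg heterozygosity `2p(1 − p)` over every
bp in `[a_j − 5000, b_j + 5000]` (clamped to the chromosome; the denominator
counts the clamped positions, e.g. a tract at 100–200 averages over
positions 1–5,200). Sites with MAF below 5% are set to `p = 0`, mirroring
the detection method's frequency filter; non-variant positions contribute
zero to the numerator but count in the denominator. A penetrance multiplier
`ρ` (default 1.0) can scale `ψ̂_j` downward when not every heterozygous site
inside a tract is converted; no attempt is made to estimate `ρ`.

## Fitting, model choice, uncertainty

Each family is fitted by maximizing the truncated log-likelihood with
L-BFGS-B on the rate scale under box constraints `(1e-8, 1 − 1e-8)`,
objective tolerance 1e-8; all arithmetic is in log space (`log1p`/`expm1`
forms keep the geometric-series normalizers accurate at extreme rates). The
mixture is optimized over a fixed grid of mixing weights — 0.002 to 0.01 in
steps of 0.00025, then 0.05 to 0.5 in steps of 0.05 — with four rate-scale
starting pairs `(0.0005, 0.1)²` per grid value; the best joint likelihood
across grid and starts wins, ties resolved toward the smaller weight, and
components are reported sorted by mean descending with `w1` the long
component's weight. Rate-boundary solutions are flagged, not raised.

Families are compared by BIC = `k ln(n) − 2 logL` with `k = 1/1/3`
parameters and `n` the retained-tract count; exact ties prefer the simpler
family. Confidence intervals are percentile bootstrap: (length, ψ̂) pairs
are resampled jointly with replacement, each resample refitted, and the
0.025/0.975 quantiles of each parameter (including the overall mean) taken.
The default is 500 resamples for data analysis; the simulation experiment
defaults to 100 resamples per replicate to keep 100-replicate coverage runs
tractable at desk scale. One root seed spawns independent child streams per
resample, so every stochastic path is reproducible.

Note a structural identifiability caveat: under truncation the likelihood
only constrains the shape of `L` inside the window, so the mixture's overall
mean — which depends on the below-window mass split between components — can
be poorly determined when the data were not generated by a two-component
mixture. BIC reliably discounts these spurious mixture solutions, but
single-family mixture estimates on misspecified data should be read with
care.

## Synthetic panel and overlay experiment

The simulator builds a diploid panel over one 10 Mb region: common-variant
positions from a homogeneous Poisson process with one MAF ≥ 5% site per
450 bp (≈7M common SNVs over a 3 Gb genome), per-site MAF from the
neutral-like `1/x` spectrum truncated to `[0.05, 0.5]`, and independent
per-individual heterozygosity `2p(1 − p)`. The default panel holds 1,000
individuals; overlay draws individuals with replacement, so the panel size
only sets the granularity of re-use, while the site density and MAF law —
which determine the ψ regime (≈6e-4, matching biobank-scale common-variant
data) — carry the statistical structure. The panel deliberately has **no
linkage disequilibrium** and no variant clustering: the estimator
conditions only on per-position heterozygosity, and excluding 1 bp spans
removes the regime where LD matters most. Consequences: effects that flow
from realistic variant clustering (e.g. small residual biases of a few bp
in otherwise well-specified fits) are not reproduced by passing tests here.

The overlay experiment mirrors the benchmark robustness design: 10,000
individuals sampled with replacement × 100 tracts each per replicate
(1,000,000 tracts), uniform start positions, true lengths from one of ten
generating distributions (geometric / sum of two / sum of three geometrics
at means 21 and 100 bp, discrete uniform on 1..41 and 1..199, and two
mixtures), observed spans taken between the outermost heterozygous sites
inside each tract, tracts overhanging the region clipped at the boundary
(negligible at 10 Mb with means ≤ 100 bp). Each replicate subsamples 50
(mean-21 generators) or 1,000 (mean-100 generators) spans inside [2, 1500]
without replacement, attaches ψ̂ from the panel's own frequency track, fits
the requested families, and records estimates, bootstrap CIs and the BIC
winner. Summaries report empirical bias, SD, CI coverage of the true mean
and selection counts over 100 replicates.

## Numerical and design choices

* Coordinates are 1-based inclusive; observed length is `b − a + 1`, so a
  single converted site has span 1. BED input (0-based half-open) is
  converted on read.
* Hotspot calling walks the genetic map greedily: from each anchor, the next
  anchor is the nearest position ≥ 2 kb away; interval rate is ΔcM/Δbp as
  cM/Mb. The genome-wide rate is pooled (total cM / total Mb). Intervals
  with rate > 10× the genome-wide average are hotspots, adjacent qualifying
  intervals merged. Intervals are half-open `[start, end)`; tract midpoints
  are `floor((a + b)/2)`; midpoint containment (not overlap) defines the
  hotspot stratum, avoiding length-dependent ascertainment.
* The truncated normalizers use closed geometric/arithmetico-geometric sums
  in `expm1` form; the window lower bound must be ≥ 2 for the ψ-cancelled
  fitting paths, while windows including 1 fall back to an explicit
  marginal-ratio computation.
* `ψ̂ = 0` tracts are legal for the geometric family (which ignores ψ) and
  rejected with a clear error by the ψ-dependent fitters.
* Fit determinism: single-threaded, fixed grid/starts, seeded bootstrap; two
  runs from the same inputs and seed produce identical output (optimizer
  results may differ in the last few floating-point digits under input
  permutation, since summation order changes the objective at machine
  precision).

## Limitations

* The panel's independence assumptions understate span shrinkage caused by
  variant clustering in real genomes; misspecification biases that depend on
  the in-window mix of long and short tracts (mixture-truth scenarios) are
  sensitive to the panel's ψ regime.
* Only two mixture components are supported; complex/long (> 1.5 kb) events
  are out of scope by construction of the truncation window.
* No estimation of penetrance; no modeling of LD.
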