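# gctract

Inference of the length distribution of non-crossover gene conversion
tracts from population-scale detections.

## The problem

Gene conversion events copy short tracts of DNA between homologous
chromosomes. Detection methods based on identity-by-descent sharing in
biobank sequence data only see the positions where an allele actually
changed, so each detected tract yields the *observed* span `L` between the
outermost converted positions, not the *true* tract length `N`. Short
tracts that convert no or one heterozygous site are invisible or appear as
a single point, and detection caps usable spans at 1.5 kb. `gctract` is for
statistical geneticists who have a table of detected tracts and want the
distribution of `N`.

The model: conditional on `N = n` and a per-bp allele conversion
probability ψ,

    P(L=0|n) = (1−ψ)^n,  P(L=1|n) = nψ(1−ψ)^{n−1},
    P(L=l|n) = (n−l+1) ψ² (1−ψ)^{n−l}   (2 ≤ l ≤ n),

with `N` geometric (mean φ), a sum of two i.i.d. geometrics, or a
two-component geometric mixture (φ1, φ2, w1). Closed-form marginals of `L`
are truncated to the retained span window `[2, 1500]` and fitted by maximum
likelihood (L-BFGS-B on the rate scale; a grid over w1 with multistart for
the mixture); ψ is estimated per tract from local heterozygosity
`2p(1−p)` in a ±5 kb window with MAF < 5% sites zeroed. Families are
compared by BIC and uncertainty comes from a percentile bootstrap. A
crossover-hotspot module stratifies tracts by midpoint containment, and a
synthetic panel/overlay simulator validates the whole pipeline. See
`docs/methods.md` for the full model and design notes.

## Worked example

Simulate a panel, overlay mixture-distributed tracts, and fit all three
families end to end:

```python
import warnings
from gctract import (GeneratorSpec, ObservedTract, ObservedTractSet,
                     fit_command, overlay_tracts, simulate_panel)

panel = simulate_panel(region_length=5_000_000, n_individuals=500, seed=7)
spec = GeneratorSpec("mixture", phi1=725, phi2=17.5, w1=0.005)  # mean 21.0 bp
ov = overlay_tracts(panel, spec, individuals_sampled=10_000,
                    tracts_per_individual=100, seed=8)
keep = ov.lengths >= 1
tracts = [ObservedTract("sim1", int(a), int(b))
          for a, b in zip(ov.a[keep], ov.b[keep])]
tset = ObservedTractSet(tracts)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = fit_command(tset, {"sim1": panel.frequency_track()},
                         families=("geometric", "geom2", "mixture"),
                         n_boot=100, seed=9)
print(report["selected"], report["selected_fit"]["estimates"])
```

Output from this exact run:

```
total observed tracts: 12656   retained in [2, 1500]: 525
geometric  mean 499.0 bp   BIC 7361.0
geom2      mean 697.7 bp   BIC 7383.0
mixture    mean  30.4 bp   BIC 7263.9   (phi1=750.1, phi2=23.1, w1=0.010)
selected: mixture   95% CI for the mean: [22.2, 63.4] bp
```

The BIC picks the mixture and its overall mean (30.4 bp, CI covering the
true 21.0 bp at n=525) is sane, while forcing a single geometric inflates
the mean to ~500 bp — the rare long component dominates the retained spans.
This misspecification inflation is exactly why model selection matters for
tract-length estimation.

The same pipeline is scriptable from the shell: `gctract simulate-panel`,
`overlay`, `fit`, `experiment`, `hotspots`, `stratify`, `sweep`
(see `gctract --help`).

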