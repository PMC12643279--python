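"""Per-tract allele conversion probability from local heterozygosity.

A detected tract's allele conversion probability ``psi_j`` is the chance that
any given bp inside the tract is observed as converted. Conversions are only
observable at heterozygous common-variant sites, so ``psi_j`` is estimated by
averaging the Hardy-Weinberg heterozygosity ``2 p (1 - p)`` over every bp in a
window extending ``flank`` bp beyond the tract on each side, with ``p`` set to
zero at positions whose minor allele frequency is below ``maf_min`` (mirroring
the detection method's MAF >= 5% filter). Positions with no variant contribute
zero to the numerator but still count in the denominator. Windows are clamped
to the chromosome, and the denominator counts only the clamped positions.

Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["FrequencyTrack", "ObservedTract", "estimate_psi", "attach_psi"]


@dataclass
class FrequencyTrack:
    """Sorted per-chromosome variant positions with minor allele frequencies."""

    chromosome: str
    positions: np.ndarray
    maf: np.ndarray
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.positions.shape != self.maf.shape:
            raise ValueError("positions and maf must have equal length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any((self.maf < 0) | (self.maf > 0.5)):
            raise ValueError("maf values must lie in [0, 0.5]")
        if self.chrom_length is None:
            self.chrom_length = int(self.positions[-1]) if self.positions.size else 0
        if self.positions.size and self.positions[-1] > self.chrom_length:
            raise ValueError("positions exceed chrom_length")
        if self.positions.size and self.positions[0] < 1:
            raise ValueError("positions are 1-based; found position < 1")

    def _het_cumsum(self, maf_min: float) -> np.ndarray:
        p = np.where(self.maf >= maf_min, self.maf, 0.0)
        return np.concatenate([[0.0], np.cumsum(2.0 * p * (1.0 - p))])


@dataclass
class ObservedTract:
    """One detected gene conversion tract (1-based inclusive coordinates)."""

    chromosome: str
    a: int
    b: int
    psi_hat: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.a > self.b:
            raise ValueError(f"require a <= b, got a={self.a}, b={self.b}")
        if self.a < 1:
            raise ValueError("coordinates are 1-based; a must be >= 1")

    @property
    def length(self) -> int:
        """Observed length: inclusive span between outermost conversions."""
        return self.b - self.a + 1

    @property
    def midpoint(self) -> int:
        return (self.a + self.b) // 2


def _psi_windows(a, b, track: FrequencyTrack, flank: int, maf_min: float,
                 penetrance: float) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    lo = np.maximum(a - flank, 1)
    hi = np.minimum(b + flank, track.chrom_length)
    denom = hi - lo + 1
    if np.any(denom <= 0):
        raise ValueError("degenerate averaging window (empty after clamping)")
    cs = track._het_cumsum(maf_min)
    i0 = np.searchsorted(track.positions, lo, side="left")
    i1 = np.searchsorted(track.positions, hi, side="right")
    num = cs[i1] - cs[i0]
    return penetrance * num / denom


def estimate_psi(tract: ObservedTract, track: FrequencyTrack, flank: int = 5000,
                 maf_min: float = 0.05, penetrance: float = 1.0) -> float:
    """Estimate the allele conversion probability for one tract.

    ``psi_hat = penetrance * mean over bp in [a - flank, b + flank] (clamped
    to the chromosome) of 2 p (1 - p)``, with ``p = 0`` below ``maf_min`` and
    at non-variant positions.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if tract.chromosome != track.chromosome:
        raise ValueError(
            f"tract on {tract.chromosome!r} but track is {track.chromosome!r}"
        )
    psi = float(_psi_windows(tract.a, tract.b, track, flank, maf_min, penetrance)[()])
    if psi == 0.0:
        warnings.warn(
            f"psi_hat = 0 for tract {tract.chromosome}:{tract.a}-{tract.b}; "
            "tract is uninformative under psi-dependent models",
            stacklevel=2,
        )
    return psi


def attach_psi(tracts: Sequence[ObservedTract],
               tracks: Mapping[str, FrequencyTrack],
               flank: int = 5000, maf_min: float = 0.05,
               penetrance: float = 1.0) -> list[ObservedTract]:
    """Populate ``psi_hat`` on every tract (order preserved).

    ``tracks`` maps chromosome name to its :class:`FrequencyTrack`; a tract on
    a chromosome without a track is an error.
    """
    missing = {t.chromosome for t in tracts} - set(tracks)
    if missing:
        raise KeyError(f"no frequency track for chromosome(s): {sorted(missing)}")
    by_chrom: dict[str, list[int]] = {}
    for idx, t in enumerate(tracts):
        by_chrom.setdefault(t.chromosome, []).append(idx)
    out = list(tracts)
    for chrom, idxs in by_chrom.items():
        track = tracks[chrom]
        a = np.array([tracts[i].a for i in idxs])
        b = np.array([tracts[i].b for i in idxs])
        psis = _psi_windows(a, b, track, flank, maf_min, penetrance)
        n_zero = int(np.sum(psis == 0.0))
        if n_zero:
            warnings.warn(
                f"{n_zero} tract(s) on {chrom} have psi_hat = 0 and are "
                "uninformative under psi-dependent models",
                stacklevel=2,
            )
        for i, psi in zip(idxs, psis):
            t = tracts[i]
            out[i] = ObservedTract(t.chromosome, t.a, t.b, psi_hat=float(psi))
    return out
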