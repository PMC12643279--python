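"""Crossover hotspot calling from a genetic map and tract stratification.

Local crossover rates are computed by a greedy walk along the map: starting
from the first mapped position, the next anchor is the closest position at
least ``min_spacing`` bp away, the rate over the spanned interval is
``delta cM / delta bp`` rescaled to cM/Mb, and the walk continues from that
anchor until no further position qualifies. Intervals whose rate exceeds
``multiplier`` times the genome-wide average (pooled total cM over total Mb)
are hotspots; adjacent qualifying intervals are merged. Tracts are stratified
by whether their midpoint (floor of the coordinate average) falls inside a
hotspot interval; intervals are half-open ``[start, end)`` on 1-based
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .psi import ObservedTract

__all__ = [
    "GeneticMap",
    "HotspotSet",
    "local_rates",
    "genomewide_rate",
    "call_hotspots",
    "stratify_by_midpoint",
]


@dataclass
class GeneticMap:
    """Cumulative genetic map for one chromosome (positions bp, cm in cM)."""

    chromosome: str
    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.positions.shape != self.cm.shape:
            raise ValueError("positions and cm must have equal length")
        if self.positions.size < 1:
            raise ValueError("empty genetic map")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cumulative cM must be nondecreasing")


@dataclass
class HotspotSet:
    """Per-chromosome non-overlapping hotspot intervals, half-open [start, end)."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)
    genomewide_rate: float = 0.0
    threshold_multiplier: float = 10.0

    def contains(self, chrom: str, pos) -> np.ndarray:
        """Vectorized midpoint-containment test."""
        pos = np.asarray(pos)
        iv = self.intervals.get(chrom)
        if iv is None or len(iv) == 0:
            return np.zeros(pos.shape, dtype=bool)
        starts, ends = iv[:, 0], iv[:, 1]
        k = np.searchsorted(starts, pos, side="right") - 1
        ok = k >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < ends[k[ok]]
        return out


def local_rates(gmap: GeneticMap, min_spacing: int = 2000) -> list[tuple[tuple[int, int], float]]:
    """Greedy-walk local crossover rates, as ((start, end), rate cM/Mb) pairs."""
    if gmap.positions.size < 2:
        raise ValueError("genetic map needs at least two positions")
    out = []
    pos, cm = gmap.positions, gmap.cm
    i = 0
    n = pos.size
    while True:
        j = int(np.searchsorted(pos, pos[i] + min_spacing, side="left"))
        if j >= n:
            break
        rate = (cm[j] - cm[i]) / (pos[j] - pos[i]) * 1e6  # cM/bp -> cM/Mb
        out.append(((int(pos[i]), int(pos[j])), float(rate)))
        i = j
    return out


def genomewide_rate(maps: Iterable[GeneticMap]) -> float:
    """Pooled genome-wide crossover rate: total cM over total Mb."""
    total_cm = 0.0
    total_bp = 0
    for m in maps:
        total_cm += float(m.cm[-1] - m.cm[0])
        total_bp += int(m.positions[-1] - m.positions[0])
    if total_bp == 0:
        raise ValueError("genetic maps span zero physical distance")
    return total_cm / total_bp * 1e6


def call_hotspots(rates_by_chrom: dict[str, list[tuple[tuple[int, int], float]]],
                  genomewide: float, multiplier: float = 10.0) -> HotspotSet:
    """Intervals with rate > multiplier * genomewide; adjacent ones merged."""
    threshold = multiplier * genomewide
    intervals: dict[str, np.ndarray] = {}
    for chrom, rates in rates_by_chrom.items():
        merged: list[list[int]] = []
        for (start, end), rate in rates:
            if rate > threshold:
                if merged and merged[-1][1] == start:
                    merged[-1][1] = end
                else:
                    merged.append([start, end])
        intervals[chrom] = np.asarray(merged, dtype=np.int64).reshape(-1, 2)
    return HotspotSet(intervals=intervals, genomewide_rate=genomewide,
                      threshold_multiplier=multiplier)


def stratify_by_midpoint(tracts: Sequence[ObservedTract], hotspots: HotspotSet,
                         ) -> tuple[list[ObservedTract], list[ObservedTract]]:
    """Partition tracts into (inside-hotspot, outside) by midpoint containment.

    The partition is exhaustive and disjoint:
    ``len(inside) + len(outside) == len(tracts)``.
    """
    inside: list[ObservedTract] = []
    outside: list[ObservedTract] = []
    by_chrom: dict[str, list[ObservedTract]] = {}
    for t in tracts:
        by_chrom.setdefault(t.chromosome, []).append(t)
    for chrom, ts in by_chrom.items():
        mids = np.array([t.midpoint for t in ts])
        hit = hotspots.contains(chrom, mids)
        for t, h in zip(ts, hit):
            (inside if h else outside).append(t)
    return inside, outside
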