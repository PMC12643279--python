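"""Readers, writers, configuration and the high-level analysis entry points.

File formats (all plain text):

* tract table — TSV with columns ``chrom  a  b``; 1-based inclusive by
  default, or 0-based half-open with ``coordinate_mode='bed'``;
* frequency track — TSV with columns ``chrom  pos  maf`` (1-based), or a
  sites-only VCF with an ``AF`` INFO field (requires cyvcf2);
* genetic map — TSV with columns ``chrom  pos  cm`` (cumulative cM), or
  PLINK ``.map`` column order (``chrom  id  cm  pos``) with ``plink=True``;
* hotspot intervals — BED (0-based half-open on output);
* fit reports — JSON; fitted-pmf curves and sweep tables — TSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .hotspots import GeneticMap, HotspotSet
from .inference import FitResult, bootstrap_ci, fit_family, select_model
from .models import TruncationWindow, log_marginal_pmf
from .psi import FrequencyTrack, ObservedTract, attach_psi

logger = logging.getLogger("gctract")

__all__ = [
    "ObservedTractSet",
    "RunConfig",
    "read_tracts",
    "read_frequency_track",
    "read_genetic_map",
    "write_hotspots_bed",
    "read_hotspots_bed",
    "fit_command",
    "fitted_pmf_curve",
    "truncation_sweep",
    "write_report",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class ObservedTractSet:
    """A collection of detected tracts plus the truncation window in force."""

    tracts: list[ObservedTract]
    window: TruncationWindow = field(default_factory=TruncationWindow)

    def __post_init__(self) -> None:
        lengths = self.lengths
        n_short = int(np.sum(lengths < self.window.lmin))
        n_long = int(np.sum(lengths > self.window.lmax))
        logger.info(
            "tract set: %d total, %d retained in [%d, %d], %d below window "
            "(l=1: %d), %d above window",
            len(self.tracts), len(self.retained_indices),
            self.window.lmin, self.window.lmax, n_short,
            int(np.sum(lengths == 1)), n_long,
        )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([t.length for t in self.tracts], dtype=np.int64)

    @property
    def psi(self) -> np.ndarray:
        return np.array(
            [np.nan if t.psi_hat is None else t.psi_hat for t in self.tracts]
        )

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(self.window.contains(self.lengths))

    def retained(self) -> tuple[np.ndarray, np.ndarray]:
        """(lengths, psi) of tracts inside the truncation window."""
        idx = self.retained_indices
        return self.lengths[idx], self.psi[idx]

    def with_psi(self, tracks: dict[str, FrequencyTrack], flank: int = 5000,
                 maf_min: float = 0.05, penetrance: float = 1.0) -> "ObservedTractSet":
        tracts = attach_psi(self.tracts, tracks, flank=flank,
                            maf_min=maf_min, penetrance=penetrance)
        return ObservedTractSet(tracts, self.window)


@dataclass
class RunConfig:
    """Aggregated tunables for an end-to-end fit run."""

    tract_path: str | None = None
    frequency_path: str | None = None
    genetic_map_path: str | None = None
    coordinate_mode: str = "1based"
    lmin: int = 2
    lmax: int = 1500
    flank: int = 5000
    maf_min: float = 0.05
    penetrance: float = 1.0
    n_boot: int = 500
    hotspot_multiplier: float = 10.0
    min_spacing: int = 2000
    seed: int | None = None
    families: tuple[str, ...] = ("geometric", "geom2", "mixture")

    @property
    def window(self) -> TruncationWindow:
        return TruncationWindow(self.lmin, self.lmax)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "families" in data:
            data["families"] = tuple(data["families"])
        return cls(**data)


def read_tracts(path, coordinate_mode: str = "1based",
                window: TruncationWindow = TruncationWindow()) -> ObservedTractSet:
    """Read a tract table TSV into an :class:`ObservedTractSet`.

    ``coordinate_mode='1based'`` expects columns chrom, a, b (1-based
    inclusive; length b - a + 1); ``'bed'`` expects 0-based half-open
    start/end (length end - start). Malformed rows raise with the line
    number.
    """
    if coordinate_mode not in {"1based", "bed"}:
        raise ValueError("coordinate_mode must be '1based' or 'bed'")
    tracts: list[ObservedTract] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and not _is_int(fields[1]):
                continue  # header row
            try:
                chrom, a, b = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            if coordinate_mode == "bed":
                a, b = a + 1, b  # half-open end == inclusive end here
            if a > b:
                raise ValueError(f"{path}:{lineno}: a > b ({a} > {b})")
            tracts.append(ObservedTract(chrom, a, b))
    return ObservedTractSet(tracts, window)


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


def read_frequency_track(path, chrom_lengths: dict[str, int] | None = None,
                         ) -> dict[str, FrequencyTrack]:
    """Read a chrom/pos/maf TSV into per-chromosome frequency tracks."""
    df = pd.read_csv(path, sep=r"\s+", comment="#",
                     names=["chrom", "pos", "maf"], dtype={"chrom": str})
    if not np.issubdtype(df["pos"].dtype, np.number):  # header present
        df = df.iloc[1:].astype({"pos": np.int64, "maf": float})
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        out[str(chrom)] = FrequencyTrack(
            chromosome=str(chrom),
            positions=grp["pos"].to_numpy(np.int64),
            maf=grp["maf"].to_numpy(float),
            chrom_length=(chrom_lengths or {}).get(str(chrom)),
        )
    return out


def read_frequency_track_vcf(path, chrom_lengths=None) -> dict[str, FrequencyTrack]:
    """Extract per-chromosome MAF tracks from a sites-only VCF (AF INFO field)."""
    from cyvcf2 import VCF  # optional dependency

    rows: dict[str, list[tuple[int, float]]] = {}
    for rec in VCF(str(path)):
        if not rec.is_snp:
            continue
        af = rec.INFO.get("AF")
        if af is None:
            continue
        af = float(af[0] if isinstance(af, (tuple, list)) else af)
        maf = min(af, 1.0 - af)
        rows.setdefault(rec.CHROM, []).append((rec.POS, maf))
    out = {}
    for chrom, pairs in rows.items():
        pairs.sort()
        pos = np.array([p for p, _ in pairs], dtype=np.int64)
        maf = np.array([m for _, m in pairs])
        out[chrom] = FrequencyTrack(chrom, pos, maf,
                                    (chrom_lengths or {}).get(chrom))
    return out


def read_genetic_map(path, plink: bool = False) -> dict[str, GeneticMap]:
    """Read a genetic map TSV (chrom/pos/cm, or PLINK chrom/id/cm/pos)."""
    names = ["chrom", "id", "cm", "pos"] if plink else ["chrom", "pos", "cm"]
    df = pd.read_csv(path, sep=r"\s+", comment="#", names=names,
                     dtype={"chrom": str})
    if not _is_int(str(df.iloc[0]["pos"])):
        df = df.iloc[1:]
    df = df.astype({"pos": np.int64, "cm": float})
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        out[str(chrom)] = GeneticMap(str(chrom), grp["pos"].to_numpy(np.int64),
                                     grp["cm"].to_numpy(float))
    return out


def write_hotspots_bed(hotspots: HotspotSet, path) -> None:
    """Write hotspot intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(hotspots.intervals):
            for start, end in hotspots.intervals[chrom]:
                fh.write(f"{chrom}\t{start - 1}\t{end - 1}\n")


def read_hotspots_bed(path, genomewide: float = 0.0,
                      multiplier: float = 10.0) -> HotspotSet:
    intervals: dict[str, list[list[int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, start, end = line.split()[:3]
            intervals.setdefault(chrom, []).append([int(start) + 1, int(end) + 1])
    return HotspotSet(
        intervals={c: np.asarray(v, np.int64) for c, v in intervals.items()},
        genomewide_rate=genomewide, threshold_multiplier=multiplier,
    )


def fit_command(tract_set: ObservedTractSet,
                tracks: dict[str, FrequencyTrack] | None = None,
                families: Sequence[str] = ("geometric", "geom2", "mixture"),
                n_boot: int = 500, seed: int | None = None,
                flank: int = 5000, maf_min: float = 0.05,
                penetrance: float = 1.0, bootstrap: bool = True,
                mixture_kwargs: dict | None = None) -> dict:
    """Full fit: attach psi, fit families, select by BIC, bootstrap the winner.

    ``tracks`` may be omitted only when fitting the geometric family alone
    (its truncated likelihood is psi-free).
    """
    needs_psi = any(f != "geometric" for f in families)
    if needs_psi and tracks is None:
        raise ValueError("a frequency track is required for psi-dependent families")
    if tracks is not None:
        tract_set = tract_set.with_psi(tracks, flank=flank, maf_min=maf_min,
                                       penetrance=penetrance)
    lengths, psi = tract_set.retained()
    if tracks is None:
        psi = None
    window = tract_set.window
    fits: dict[str, FitResult] = {}
    for fam in families:
        kw = dict(mixture_kwargs or {}) if fam == "mixture" else {}
        fits[fam] = fit_family(fam, lengths, psi, window, **kw)
    best = select_model(list(fits.values())) if len(fits) > 1 else next(iter(fits.values()))
    if bootstrap and n_boot > 0:
        boot = bootstrap_ci(lengths, psi, family=best.family, n_boot=n_boot,
                            seed=seed, window=window,
                            **(dict(mixture_kwargs or {}) if best.family == "mixture" else {}))
        best.ci = boot["ci"]
        best.boot = boot
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "window": [window.lmin, window.lmax],
        "n_retained": int(lengths.size),
        "seed": seed,
        "fits": {fam: fr.to_dict() for fam, fr in fits.items()},
        "selected": best.family,
        "selected_fit": best.to_dict(),
    }


def fitted_pmf_curve(fit: FitResult, psis, lmax: int | None = None,
                     ) -> pd.DataFrame:
    """Psi-averaged fitted pmf: mean_j P(L = l | psi_hat_j) for l = 1..lmax.

    This is the untruncated marginal (so the curve includes l = 1 and its
    total mass over 1..lmax is below one, the remainder being the mass at
    l = 0 and beyond lmax).
    """
    psis = np.asarray(psis, dtype=float).reshape(-1)
    lmax = fit.window.lmax if lmax is None else lmax
    grid = np.arange(1, lmax + 1)
    acc = np.zeros(grid.size)
    for start in range(0, psis.size, 512):
        block = psis[start:start + 512]
        lp = log_marginal_pmf(fit.model, grid[None, :], block[:, None])
        acc += np.exp(lp).sum(axis=0)
    return pd.DataFrame({"l": grid, "probability": acc / psis.size})


def truncation_sweep(tract_set: ObservedTractSet,
                     tracks: dict[str, FrequencyTrack] | None = None,
                     bounds: Sequence[int] = (1500, 2000, 3000),
                     families: Sequence[str] = ("geometric", "geom2", "mixture"),
                     **fit_kwargs) -> dict[int, dict]:
    """Refit every family with the upper truncation bound swept over ``bounds``.

    Returns ``{bound: fit_command report}``; the overall-mean trajectory per
    family across bounds is the headline sensitivity diagnostic.
    """
    out = {}
    for bound in bounds:
        window = TruncationWindow(tract_set.window.lmin, int(bound))
        subset = ObservedTractSet(tract_set.tracts, window)
        out[int(bound)] = fit_command(subset, tracks, families=families,
                                      bootstrap=False, **fit_kwargs)
    return out


def write_bootstrap_draws(boot: dict, path) -> None:
    """Dump per-resample bootstrap parameter draws as TSV."""
    pd.DataFrame(boot["draws"]).to_csv(path, sep="\t", index=False)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
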