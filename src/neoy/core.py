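"""Shared coordinate, genotype and window containers.

Coordinate conventions follow the formats they mirror: :class:`Region` and all
windows are BED-style 0-based half-open; genotype site positions are VCF-style
1-based.  The conversion happens once, at the reader boundary in
:mod:`neoy.io`.
"""

from __future__ import annotations

import dataclasses
import zlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MALE = "male"
FEMALE = "female"

#: genotype codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing
GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING = 0, 1, 2, -1


@dataclasses.dataclass(frozen=True)
class Region:
    """A 0-based half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("Region.chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"Region requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.span

    def contains(self, pos0: int) -> bool:
        """Whether the 0-based position falls inside the region."""
        return self.start <= pos0 < self.end

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "Region") -> "Region | None":
        if not self.overlaps(other):
            return None
        return Region(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )


class WindowTrack:
    """Per-window statistic series along one chromosome.

    Windows are non-overlapping tiling intervals by default (the last window is
    truncated at the region end).  ``mask`` is True where a window carries
    valid values; masked windows hold NaN in every statistic.
    """

    def __init__(
        self,
        chrom: str,
        starts: np.ndarray,
        ends: np.ndarray,
        span: int | None = None,
    ) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if starts.shape != ends.shape or starts.ndim != 1 or starts.size == 0:
            raise ValueError("starts/ends must be matching non-empty 1-D arrays")
        if np.any(ends <= starts):
            raise ValueError("every window needs end > start")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("windows must be non-overlapping and ordered")
        self.chrom = chrom
        self.starts = starts
        self.ends = ends
        self.span = int(span if span is not None else (ends[0] - starts[0]))
        self.mask = np.ones(starts.size, dtype=bool)
        self.values: dict[str, np.ndarray] = {}

    # -- construction -----------------------------------------------------
    @classmethod
    def from_arrays(
        cls, chrom, starts, ends, values=None, mask=None
    ) -> "WindowTrack":
        t = cls(chrom, starts, ends)
        if mask is not None:
            t.mask = np.asarray(mask, dtype=bool).copy()
        for name, v in (values or {}).items():
            t.set_stat(name, v)
        return t

    @property
    def n(self) -> int:
        return self.starts.size

    def set_stat(self, name: str, vals, valid=None) -> None:
        vals = np.asarray(vals, dtype=float).copy()
        if vals.shape != self.starts.shape:
            raise ValueError(f"statistic {name!r} has wrong length")
        if valid is not None:
            self.mask &= np.asarray(valid, dtype=bool)
        vals[~self.mask] = np.nan
        self.values[name] = vals

    def stat(self, name: str) -> np.ndarray:
        return self.values[name]

    def window_index(self, pos0) -> np.ndarray:
        """Tiling-window index of 0-based positions (-1 if outside the track)."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        idx = (pos0 - self.starts[0]) // self.span
        idx = np.where((pos0 >= self.starts[0]) & (pos0 < self.ends[-1]), idx, -1)
        return np.clip(idx, -1, self.n - 1)

    def regions(self) -> list[Region]:
        return [Region(self.chrom, int(s), int(e)) for s, e in zip(self.starts, self.ends)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "start": self.starts, "end": self.ends})
        for name, v in self.values.items():
            df[name] = v
        df["masked"] = (~self.mask).astype(int)
        return df


def make_windows(region: Region, span: int, step: int | None = None) -> WindowTrack:
    """Tile ``region`` with fixed-span windows (the last one truncated).

    ``step`` defaults to ``span`` (non-overlapping tiling).  A span at least as
    large as the region yields a single window.
    """
    if span <= 0:
        raise ValueError("window span must be positive")
    step = span if step is None else int(step)
    if step <= 0:
        raise ValueError("window step must be positive")
    starts = np.arange(region.start, region.end, step, dtype=np.int64)
    ends = np.minimum(starts + span, region.end)
    keep = starts < ends
    t = WindowTrack(region.chrom, starts[keep], ends[keep], span=span)
    return t


class GenotypeMatrix:
    """Biallelic genotype codes for sexed samples at genomic sites.

    ``geno`` is an ``(n_sites, n_samples)`` int8 array with codes 0/1/2/-1.
    ``sites`` is a DataFrame with columns ``chrom``, ``pos`` (1-based),
    ``ref``, ``alt``; positions are strictly increasing within a chromosome.
    """

    def __init__(
        self,
        samples: Sequence[str],
        sex: Sequence[str],
        sites: pd.DataFrame,
        geno: np.ndarray,
    ) -> None:
        self.samples = list(samples)
        self.sex = np.asarray(sex, dtype=object)
        self.sites = sites.reset_index(drop=True)
        self.geno = np.asarray(geno, dtype=np.int8)
        if self.sex.shape[0] != len(self.samples):
            raise ValueError("one sex label per sample required")
        bad = set(self.sex) - {MALE, FEMALE}
        if bad:
            raise ValueError(f"invalid sex labels: {sorted(bad)}")
        if self.geno.shape != (len(self.sites), len(self.samples)):
            raise ValueError("geno shape must be (n_sites, n_samples)")
        for _, grp in self.sites.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("site positions must increase within a chromosome")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_male(self) -> np.ndarray:
        return self.sex == MALE

    @property
    def is_female(self) -> np.ndarray:
        return self.sex == FEMALE

    def site_mask(self, region: Region) -> np.ndarray:
        """Boolean mask of sites falling inside a 0-based half-open region."""
        pos0 = self.sites["pos"].to_numpy() - 1
        return (
            (self.sites["chrom"].to_numpy() == region.chrom)
            & (pos0 >= region.start)
            & (pos0 < region.end)
        )

    def subset_sites(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.samples, self.sex, self.sites.loc[mask], self.geno[mask]
        )

    def subset_region(self, region: Region) -> "GenotypeMatrix":
        return self.subset_sites(self.site_mask(region))


@dataclasses.dataclass
class SimTruth:
    """Ground-truth sidecar written by the simulator for recovery tests.

    ``strata`` are ``(Region on Y, age in years)`` pairs tiling the non-PAR;
    planted id lists name the simulated sites/genes each detector must recover.
    """

    strata: list[tuple[Region, float]]
    inversion: Region | None
    fusion_point: int
    par: list[Region]
    planted_scs_sites: list[str]
    planted_degs: list[str]
    planted_pseudogenes: list[str]
    planted_yxminus: list[str]
    seed: int
    extras: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(age < 0 for _, age in self.strata):
            raise ValueError("stratum ages must be non-negative")
        if self.strata:
            lo = min(r.start for r, _ in self.strata)
            hi = max(r.end for r, _ in self.strata)
            if not (lo <= self.fusion_point <= hi):
                raise ValueError("fusion point must lie inside the Y non-PAR")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from one top-level seed."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def merge_flagged_windows(
    track: WindowTrack, flags: np.ndarray, max_gap: int = 1
) -> list[Region]:
    """Merge runs of flagged windows, bridging gaps of at most ``max_gap``."""
    flags = np.asarray(flags, dtype=bool)
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    regions: list[Region] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 > max_gap:
            regions.append(
                Region(track.chrom, int(track.starts[run_start]), int(track.ends[prev]))
            )
            run_start = i
        prev = i
    regions.append(
        Region(track.chrom, int(track.starts[run_start]), int(track.ends[prev]))
    )
    return regions
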