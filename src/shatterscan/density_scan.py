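"""Breakpoint extraction, density statistics and the sliding-window scan.

Every translocation contributes four breakpoints (two on the source
chromosome, two on the destination) and every CNV two.  A breakpoint
that falls on a chromosome terminus is shifted just outside the
sequence: position 0 when the variant starts at base 1, length + 1 when
it ends at the final base.

The genome is divided into contiguous bins of ``bin_size`` bp; a window
spans ``window_size`` consecutive bins and advances one bin at a time.
Windows whose breakpoint count is significantly above the genome-wide
window distribution (z >= ``window_z_threshold``) are merged into
highly mutated regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import intervals
from .io_formats import (
    CNVCall,
    GenomeModel,
    InsertionCall,
    LOHCall,
    ScanConfig,
    TranslocationCall,
)

__all__ = [
    "Breakpoint",
    "DensityStats",
    "WindowScan",
    "MutatedRegion",
    "extract_breakpoints",
    "chromosome_densities",
    "sliding_window_scan",
    "identify_mutated_regions",
]


@dataclass(frozen=True)
class Breakpoint:
    """One end of a structural variant, tagged with its origin."""

    chrom: str
    pos: int
    origin: str  # transloc_src_start, ..., cnv_start, cnv_end


def _edge(pos: int, length: int, is_start: bool) -> int:
    # terminal SV ends sit just outside the sequence
    if is_start and pos <= 1:
        return 0
    if not is_start and pos >= length:
        return length + 1
    return pos


def extract_breakpoints(
    translocations: Iterable[TranslocationCall],
    cnvs: Iterable[CNVCall],
    genome: GenomeModel,
) -> list[Breakpoint]:
    """List the four breakpoints of each translocation and two of each CNV."""
    bps: list[Breakpoint] = []
    for t in translocations:
        ls, ld = genome.length(t.src_chrom), genome.length(t.dst_chrom)
        bps.append(Breakpoint(t.src_chrom, _edge(t.src_start, ls, True), "transloc_src_start"))
        bps.append(Breakpoint(t.src_chrom, _edge(t.src_end, ls, False), "transloc_src_end"))
        bps.append(Breakpoint(t.dst_chrom, _edge(t.dst_start, ld, True), "transloc_dst_start"))
        bps.append(Breakpoint(t.dst_chrom, _edge(t.dst_end, ld, False), "transloc_dst_end"))
    for c in cnvs:
        lc = genome.length(c.chrom)
        bps.append(Breakpoint(c.chrom, _edge(c.start, lc, True), "cnv_start"))
        bps.append(Breakpoint(c.chrom, _edge(c.end, lc, False), "cnv_end"))
    return bps


@dataclass(frozen=True)
class DensityStats:
    """Per-chromosome breakpoint counts and densities (breakpoints / bp).

    ``mean`` and ``sd`` are the moments of the per-chromosome densities
    over *all* chromosomes in the genome model, zero-count ones
    included; ``sd`` is the population standard deviation.
    """

    counts: dict[str, int]
    densities: dict[str, float]
    mean: float
    sd: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chromosome": list(self.counts),
             "breakpoints": list(self.counts.values()),
             "density": [self.densities[c] for c in self.counts]}
        )


def chromosome_densities(breakpoints: Iterable[Breakpoint], genome: GenomeModel) -> DensityStats:
    """Breakpoints per bp for every chromosome, with genome-wide moments."""
    counts = {name: 0 for name in genome.names}
    for bp in breakpoints:
        counts[genome.canonical(bp.chrom)] += 1
    densities = {name: counts[name] / genome.length(name) for name in genome.names}
    values = np.array(list(densities.values()), dtype=float)
    return DensityStats(
        counts=counts,
        densities=densities,
        mean=float(values.mean()),
        sd=float(values.std()),  # population sd, deterministic on tiny inputs
    )


@dataclass
class WindowScan:
    """Per-chromosome sliding-window breakpoint counts.

    ``counts[chrom][i]`` is the number of breakpoints in window *i*,
    which spans bins ``i .. i + window_size - 1``.  Chromosomes shorter
    than one window get a single whole-chromosome window.
    """

    counts: dict[str, np.ndarray]
    bin_size: int
    window_size: int
    genome: GenomeModel

    def n_windows(self, chrom: str) -> int:
        return len(self.counts[self.genome.canonical(chrom)])

    def window_bounds(self, chrom: str, i: int) -> tuple[int, int]:
        chrom = self.genome.canonical(chrom)
        length = self.genome.length(chrom)
        if len(self.counts[chrom]) == 1:
            return 1, length
        start = i * self.bin_size + 1
        end = min((i + self.window_size) * self.bin_size, length)
        return start, end

    def all_counts(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in self.genome.names])

    def frame(self) -> pd.DataFrame:
        """One row per window: chromosome, start, end, count."""
        rows = []
        for chrom in self.genome.names:
            arr = self.counts[chrom]
            for i in range(len(arr)):
                s, e = self.window_bounds(chrom, i)
                rows.append((chrom, s, e, int(arr[i])))
        return pd.DataFrame(rows, columns=["chromosome", "start", "end", "count"])


def sliding_window_scan(
    breakpoints: Iterable[Breakpoint], genome: GenomeModel, config: ScanConfig
) -> WindowScan:
    """Count breakpoints in overlapping windows that advance one bin at a time."""
    per_chrom_pos: dict[str, list[int]] = {name: [] for name in genome.names}
    for bp in breakpoints:
        per_chrom_pos[genome.canonical(bp.chrom)].append(bp.pos)

    counts: dict[str, np.ndarray] = {}
    for name in genome.names:
        length = genome.length(name)
        n_bins = -(-length // config.bin_size)  # ceil
        pos = np.asarray(per_chrom_pos[name], dtype=np.int64)
        if pos.size:
            # sentinel positions 0 and length+1 fall into the terminal bins
            idx = np.clip((pos - 1) // config.bin_size, 0, n_bins - 1)
            bins = np.bincount(idx, minlength=n_bins).astype(np.int64)
        else:
            bins = np.zeros(n_bins, dtype=np.int64)
        if n_bins <= config.window_size:
            counts[name] = np.array([bins.sum()], dtype=np.int64)
            continue
        csum = np.concatenate([[0], np.cumsum(bins)])
        n_win = n_bins - config.window_size + 1
        counts[name] = csum[config.window_size:config.window_size + n_win] - csum[:n_win]
    return WindowScan(counts=counts, bin_size=config.bin_size,
                      window_size=config.window_size, genome=genome)


@dataclass
class MutatedRegion:
    """A merged run of significant windows with the SVs that overlap it."""

    chrom: str
    start: int
    end: int
    breakpoint_count: int
    region_density: float
    translocations: tuple[TranslocationCall, ...] = ()
    cnvs: tuple[CNVCall, ...] = ()
    lohs: tuple[LOHCall, ...] = ()
    insertions: tuple[InsertionCall, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _transloc_overlaps(t: TranslocationCall, chrom: str, start: int, end: int) -> bool:
    return (t.src_chrom == chrom and intervals.overlaps(t.src_start, t.src_end, start, end)) or (
        t.dst_chrom == chrom and intervals.overlaps(t.dst_start, t.dst_end, start, end)
    )


def identify_mutated_regions(
    scan: WindowScan,
    genome: GenomeModel,
    config: ScanConfig,
    translocations: Sequence[TranslocationCall] = (),
    cnvs: Sequence[CNVCall] = (),
    lohs: Sequence[LOHCall] = (),
    insertions: Sequence[InsertionCall] = (),
    breakpoints: Sequence[Breakpoint] = (),
) -> list[MutatedRegion]:
    """Merge significant windows into regions and attach overlapping SVs.

    Window counts are z-scaled against the mean and population standard
    deviation of *all* windows genome-wide.  When every window has the
    same count (sd = 0) the genome is uniform and no region is emitted.
    Overlapping or abutting flagged windows on one chromosome merge
    into a single region spanning from the first window's start to the
    last window's end.
    """
    all_counts = scan.all_counts()
    mean = float(all_counts.mean())
    sd = float(all_counts.std())
    if sd == 0.0:
        return []
    threshold = mean + config.window_z_threshold * sd

    regions: list[MutatedRegion] = []
    for chrom in genome.names:
        arr = scan.counts[chrom]
        marked = np.flatnonzero(arr >= threshold)
        if marked.size == 0:
            continue
        runs: list[tuple[int, int]] = []
        run_start = prev = int(marked[0])
        for i in marked[1:]:
            i = int(i)
            if i - prev <= scan.window_size:  # windows overlap or abut
                prev = i
            else:
                runs.append((run_start, prev))
                run_start = prev = i
        runs.append((run_start, prev))

        length = genome.length(chrom)
        chrom_pos = sorted(
            min(max(bp.pos, 1), length) for bp in breakpoints if genome.canonical(bp.chrom) == chrom
        )
        pos_arr = np.asarray(chrom_pos, dtype=np.int64)
        for first, last in runs:
            start = scan.window_bounds(chrom, first)[0]
            end = scan.window_bounds(chrom, last)[1]
            count = int(np.searchsorted(pos_arr, end, side="right")
                        - np.searchsorted(pos_arr, start, side="left"))
            region = MutatedRegion(
                chrom=chrom,
                start=start,
                end=end,
                breakpoint_count=count,
                region_density=count / (end - start + 1),
                translocations=tuple(
                    t for t in translocations if _transloc_overlaps(t, chrom, start, end)
                ),
                cnvs=tuple(
                    c for c in cnvs
                    if c.chrom == chrom and intervals.overlaps(c.start, c.end, start, end)
                ),
                lohs=tuple(
                    l for l in lohs
                    if l.chrom == chrom and intervals.overlaps(l.start, l.end, start, end)
                ),
                insertions=tuple(
                    i for i in insertions if i.chrom == chrom and start <= i.pos <= end
                ),
            )
            regions.append(region)
    return regions
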