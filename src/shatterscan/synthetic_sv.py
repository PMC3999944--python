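"""Synthetic structural-variant call sets with controllable hallmark intensity.

Two generators share one seeded RNG stream:

``simulate_chromothriptic``
    Plants a single shattered region on one chromosome -- oscillating
    two-state CNV segments separated by normal gaps, translocations
    whose breakpoints cluster tightly on the target and on a handful of
    partner chromosomes, short insertions near a configurable fraction
    of breakpoints, and LOH only over the deleted segments (so
    heterozygosity between CNVs is retained).  A diffuse background of
    unclustered calls is overlaid so discrimination is tested against
    realistic noise.

``simulate_background``
    The negative control: the same diffuse background alone.  CNV, LOH
    and insertion calls land uniformly across the genome (chromosome
    chosen proportional to its length) with same-chromosome CNVs kept
    well apart; copy-number states are drawn from several aberrant
    levels; translocations pair chromosomes by a random perfect
    matching and their fragments span at least half the chromosome, so
    breakpoints are as dispersed as uniform placement predicts and no
    chromosome accumulates recurrent events.  No hallmark is expressed
    beyond chance.

Both write the exact input dialects of :mod:`shatterscan.io_formats`
plus a ``truth.yaml`` record of what was planted.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io_formats import (
    CNVCall,
    GenomeModel,
    InsertionCall,
    LOHCall,
    TranslocationCall,
    write_cnvs,
    write_genome,
    write_insertions_vcf,
    write_loh,
    write_translocations,
)

__all__ = [
    "SimulationParams",
    "SimulatedSample",
    "default_genome",
    "simulate_chromothriptic",
    "simulate_background",
]

# GRCh37 autosome + sex chromosome lengths (bp)
_HG19_LENGTHS = {
    "1": 249_250_621, "2": 243_199_373, "3": 198_022_430, "4": 191_154_276,
    "5": 180_915_260, "6": 171_115_067, "7": 159_138_663, "8": 146_364_022,
    "9": 141_213_431, "10": 135_534_747, "11": 135_006_516, "12": 133_851_895,
    "13": 115_169_878, "14": 107_349_540, "15": 102_531_392, "16": 90_354_753,
    "17": 81_195_210, "18": 78_077_248, "19": 59_128_983, "20": 63_025_520,
    "21": 48_129_895, "22": 51_304_566, "X": 155_270_560, "Y": 59_373_566,
}


def default_genome() -> GenomeModel:
    """A human (GRCh37) genome model: 22 autosomes plus X and Y."""
    return GenomeModel(tuple(_HG19_LENGTHS.items()))


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults emulate the validation setting.

    The chromothriptic event: ``n_cnv_segments`` oscillating segments in
    ``region`` of ``target_chrom``, cycling through ``aberrant_states``
    (a single deletion state by default, the classic two-state
    pattern); ``n_translocations`` spread round-robin over
    ``n_partner_chromosomes`` partners with all breakpoints confined to
    ``cluster_width`` bp; insertions within 10 bp of a fraction
    ``insertion_rate`` of breakpoints; LOH only over deleted segments
    plus a fraction ``loh_gap_fraction`` of the inter-CNV gaps (0 keeps
    the retained-heterozygosity hallmark fully expressed).

    The diffuse background: the few scattered calls SV callers leave on
    unremarkable samples -- CNVs with same-chromosome midpoints at
    least ``background_min_spacing`` apart, several distinct aberrant
    copy-number states, translocations pairing chromosomes without
    recurrence, and fragments spanning ``fragment_fraction`` of their
    chromosome so partner breakpoints are as dispersed as uniform
    placement predicts.
    """

    seed: int = 0
    # planted event
    target_chrom: str = "8"
    region: tuple[int, int] = (55_000_000, 85_000_000)
    n_cnv_segments: int = 20
    aberrant_states: tuple[int, ...] = (1,)
    n_translocations: int = 24
    n_partner_chromosomes: int = 3
    cluster_width: int = 2_000_000
    insertion_rate: float = 0.5
    loh_gap_fraction: float = 0.0
    # diffuse background
    background_translocations: int = 10
    background_cnvs: int = 12
    background_insertions: int = 30
    background_loh: int = 12
    background_states: tuple[int, ...] = (0, 1, 3, 4, 5, 6)
    fragment_fraction: tuple[float, float] = (0.5, 0.95)
    background_min_spacing: int = 50_000_000

    def __post_init__(self) -> None:
        for name in ("n_cnv_segments", "n_translocations", "n_partner_chromosomes",
                     "cluster_width", "background_translocations", "background_cnvs",
                     "background_insertions", "background_loh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("insertion_rate", "loh_gap_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulatedSample:
    """Generated call lists plus the truth record of what was planted."""

    params: SimulationParams
    genome: GenomeModel
    translocations: list[TranslocationCall]
    cnvs: list[CNVCall]
    lohs: list[LOHCall]
    insertions: list[InsertionCall]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write sample.{spt,spc,spl,vcf}, genome.tsv and truth.yaml."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "translocations": outdir / "sample.spt",
            "cnvs": outdir / "sample.spc",
            "loh": outdir / "sample.spl",
            "insertions": outdir / "sample.vcf",
            "genome": outdir / "genome.tsv",
            "truth": outdir / "truth.yaml",
        }
        write_translocations(self.translocations, paths["translocations"])
        write_cnvs(self.cnvs, paths["cnvs"])
        write_loh(self.lohs, paths["loh"])
        write_insertions_vcf(self.insertions, paths["insertions"], self.genome)
        write_genome(self.genome, paths["genome"])
        with open(paths["truth"], "w") as fh:
            yaml.safe_dump(self.truth, fh, sort_keys=False)
        return paths


def _quality(rng: np.random.Generator) -> float:
    # keep defaults above any min_quality filter
    return round(float(rng.uniform(0.8, 1.0)), 4)


def _random_chrom(rng: np.random.Generator, genome: GenomeModel, probs: np.ndarray) -> str:
    return genome.names[int(rng.choice(len(genome), p=probs))]


def _diffuse_background(
    rng: np.random.Generator,
    genome: GenomeModel,
    n_translocations: int,
    n_cnvs: int,
    n_insertions: int,
    n_loh: int,
    states: Sequence[int],
    fragment_fraction: tuple[float, float],
    min_spacing: int,
) -> tuple[list[TranslocationCall], list[CNVCall], list[LOHCall], list[InsertionCall]]:
    lengths = np.array([genome.length(n) for n in genome.names], dtype=float)
    probs = lengths / lengths.sum()

    def interval(chrom: str) -> tuple[int, int]:
        length = genome.length(chrom)
        frac = rng.uniform(*fragment_fraction)
        size = max(1, int(frac * length))
        size = min(size, length - 1)
        start = int(rng.integers(1, length - size + 1))
        return start, start + size

    # translocation partners are spread maximally over the genome: chromosome
    # pairs come from a random perfect matching, so no chromosome recurs until
    # every pair has been used once (unclustered, non-recurrent rearrangements)
    translocations = []
    pairs: list[tuple[str, str]] = []
    for k in range(n_translocations):
        if not pairs:
            order = [genome.names[i] for i in rng.permutation(len(genome))]
            pairs = list(zip(order[0::2], order[1::2]))
        src, dst = pairs.pop(0)
        s1, e1 = interval(src)
        s2, e2 = interval(dst)
        translocations.append(TranslocationCall(src, s1, e1, dst, s2, e2, _quality(rng)))

    # CNV midpoints on one chromosome keep min_spacing apart: unremarkable
    # samples carry scattered, unclustered copy-number calls
    cnvs = []
    states = tuple(states) or (1,)
    midpoints: dict[str, list[int]] = {}
    for _ in range(n_cnvs):
        for _attempt in range(200):
            chrom = _random_chrom(rng, genome, probs)
            length = genome.length(chrom)
            size = int(np.clip(rng.lognormal(math.log(3e5), 0.8), 5e4, 5e6))
            size = min(size, length - 1)
            start = int(rng.integers(1, length - size + 1))
            mid = start + size // 2
            if all(abs(mid - m) >= min_spacing for m in midpoints.get(chrom, ())):
                break
        midpoints.setdefault(chrom, []).append(mid)
        cn = int(states[int(rng.integers(len(states)))])
        cnvs.append(CNVCall(chrom, start, start + size, cn, _quality(rng)))

    lohs = []
    for _ in range(n_loh):
        chrom = _random_chrom(rng, genome, probs)
        length = genome.length(chrom)
        size = min(int(rng.uniform(1e6, 5e6)), length - 1)
        start = int(rng.integers(1, length - size + 1))
        lohs.append(LOHCall(chrom, start, start + size, _quality(rng)))

    insertions = []
    for _ in range(n_insertions):
        chrom = _random_chrom(rng, genome, probs)
        pos = int(rng.integers(1, genome.length(chrom) + 1))
        insertions.append(InsertionCall(chrom, pos, int(rng.integers(1, 10))))

    return translocations, cnvs, lohs, insertions


def simulate_background(
    params: SimulationParams | None = None, genome: GenomeModel | None = None
) -> SimulatedSample:
    """Diffuse, unclustered call set: the negative control."""
    params = params or SimulationParams()
    genome = genome or default_genome()
    rng = np.random.default_rng(params.seed)
    translocations, cnvs, lohs, insertions = _diffuse_background(
        rng, genome,
        params.background_translocations, params.background_cnvs,
        params.background_insertions, params.background_loh,
        params.background_states, params.fragment_fraction, params.background_min_spacing,
    )
    truth = {"kind": "background", "seed": int(params.seed)}
    return SimulatedSample(params, genome, translocations, cnvs, lohs, insertions, truth)


def simulate_chromothriptic(
    params: SimulationParams | None = None, genome: GenomeModel | None = None
) -> SimulatedSample:
    """Background plus one planted chromothriptic region (the truth)."""
    params = params or SimulationParams()
    genome = genome or default_genome()
    if params.target_chrom not in genome:
        raise ValueError(f"target chromosome {params.target_chrom!r} not in genome")
    target = genome.canonical(params.target_chrom)
    region_start, region_end = map(int, params.region)
    if not (1 <= region_start <= region_end <= genome.length(target)):
        raise ValueError(f"region {params.region} does not fit chromosome {target}")

    rng = np.random.default_rng(params.seed)
    translocations, cnvs, lohs, insertions = _diffuse_background(
        rng, genome,
        params.background_translocations, params.background_cnvs,
        params.background_insertions, params.background_loh,
        params.background_states, params.fragment_fraction, params.background_min_spacing,
    )

    # --- oscillating CNV segments: one aberrant segment per slot -----------
    span = region_end - region_start + 1
    n_seg = params.n_cnv_segments
    if n_seg:
        slot = span // n_seg
        if slot < 1000:
            raise ValueError(
                f"cannot pack {n_seg} CNV segments into a {span} bp region"
            )
        for i in range(n_seg):
            base = region_start + i * slot
            seg_start = base + int(rng.uniform(0.15, 0.40) * slot)
            seg_len = max(1, int(rng.uniform(0.20, 0.40) * slot))
            seg_end = min(seg_start + seg_len - 1, base + slot - 1)
            state = int(params.aberrant_states[i % len(params.aberrant_states)])
            cnvs.append(CNVCall(target, seg_start, seg_end, state, _quality(rng)))
            if state < 2:  # deletions lose one allele: matching LOH call
                lohs.append(LOHCall(target, seg_start, seg_end, _quality(rng)))

    # optional erosion of retained heterozygosity between the segments
    if params.loh_gap_fraction > 0 and n_seg:
        slot = span // n_seg
        for i in range(n_seg - 1):
            gap_start = region_start + i * slot + int(0.6 * slot)
            gap_len = int(params.loh_gap_fraction * 0.4 * slot)
            if gap_len >= 1:
                lohs.append(LOHCall(target, gap_start, gap_start + gap_len - 1, _quality(rng)))

    # --- clustered translocations to a few partner chromosomes -------------
    event_breakpoints: list[tuple[str, int]] = []
    if params.n_translocations:
        others = [n for n in genome.names if n != target]
        k = min(params.n_partner_chromosomes, len(others))
        if k == 0:
            raise ValueError("no partner chromosome available")
        partners = [others[i] for i in rng.choice(len(others), size=k, replace=False)]
        centers = {
            p: int(rng.uniform(0.2, 0.8) * genome.length(p)) for p in partners
        }
        src_center = (region_start + region_end) // 2
        width = max(params.cluster_width, 1)
        for j in range(params.n_translocations):
            partner = partners[j % k]
            src_start = src_center - width // 2 + int(rng.integers(0, width))
            src_start = max(region_start, min(src_start, region_end - 1))
            src_end = min(src_start + int(rng.integers(500, 5001)), region_end)
            dst_start = centers[partner] - width // 2 + int(rng.integers(0, width))
            dst_start = max(1, min(dst_start, genome.length(partner) - 6000))
            dst_end = dst_start + int(rng.integers(500, 5001))
            translocations.append(TranslocationCall(
                target, src_start, src_end, partner, dst_start, dst_end, _quality(rng)
            ))
            event_breakpoints += [(target, src_start), (target, src_end),
                                  (partner, dst_start), (partner, dst_end)]

    # --- short insertions at a fraction of the event breakpoints -----------
    for chrom, pos in event_breakpoints:
        if rng.random() < params.insertion_rate:
            offset = int(rng.integers(0, 11)) * (1 if rng.random() < 0.5 else -1)
            insertions.append(InsertionCall(chrom, max(1, pos + offset),
                                            int(rng.integers(1, 10))))

    truth = {
        "kind": "chromothriptic",
        "chromosome": target,
        "start": region_start,
        "end": region_end,
        "seed": int(params.seed),
    }
    return SimulatedSample(params, genome, translocations, cnvs, lohs, insertions, truth)
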