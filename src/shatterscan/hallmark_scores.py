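"""The seven hallmark sub-scores computed for each highly mutated region.

Each score lives in [0, 1]; 1 means the hallmark is strongly expressed
in the region, 0 that it is absent.  The hallmarks are

1. genome localization -- the region's chromosome carries an unusually
   high SV density compared with the rest of the genome;
2. chromosome localization -- the region itself is denser than its
   chromosome (Pearson chi-squared enrichment, 1 df);
3. copy-number aberrations -- few distinct aberrant CN states but many
   oscillations between states;
4. translocation localization -- many translocations to few partner
   chromosomes, with tightly clustered partner breakpoints;
5. retained heterozygosity -- the space between CNVs keeps both alleles;
6. short insertions near translocation breakpoints;
7. TP53 mutation, a user-supplied flag.

Throughout, "significant" values are those whose z-score (computed with
the population standard deviation) exceeds a low cutoff, default -2;
this drops the bottom few percent of counts so that noise calls do not
dilute the scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from . import intervals
from .density_scan import MutatedRegion
from .io_formats import (
    CNVCall,
    GenomeModel,
    InsertionCall,
    LOHCall,
    ScanConfig,
    TranslocationCall,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HallmarkScores",
    "CNStateTally",
    "PartnerStats",
    "TranslocationResult",
    "genome_localization_score",
    "chromosome_localization_score",
    "count_significant",
    "cn_oscillations",
    "cnv_score",
    "translocation_spread",
    "translocation_score",
    "region_partner_breakpoints",
    "heterozygosity_score",
    "region_translocation_breakpoints",
    "insertion_score",
    "tp53_score",
    "tp53_scan",
]


@dataclass(frozen=True)
class HallmarkScores:
    """The seven per-region sub-scores, each in [0, 1]."""

    genome_localization: float
    chromosome_localization: float
    cnv: float
    translocation: float
    heterozygosity: float
    insertion: float
    tp53: float

    def as_dict(self) -> dict[str, float]:
        return {
            "genome_localization": self.genome_localization,
            "chromosome_localization": self.chromosome_localization,
            "cnv": self.cnv,
            "translocation": self.translocation,
            "heterozygosity": self.heterozygosity,
            "insertion": self.insertion,
            "tp53": self.tp53,
        }


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


# ---------------------------------------------------------------------------
# 1. genome localization
# ---------------------------------------------------------------------------

def genome_localization_score(chrom_density: float, mean: float, sd: float) -> float:
    """Right-tail normal score of one chromosome's SV density.

    Chromosomes at or below the genome mean score 0 (no test is
    performed, avoiding multiple testing on unenriched chromosomes).
    Above the mean, ``z = (d - mean) / sd`` is converted to a
    right-tailed p-value and mapped to ``(0.5 - p) / 0.5``, which grows
    from 0 at z = 0 towards 1 for extreme densities.
    """
    if sd == 0.0 or chrom_density <= mean:
        return 0.0
    z = (chrom_density - mean) / sd
    p = float(stats.norm.sf(z))
    return _clamp01((0.5 - p) / 0.5)


# ---------------------------------------------------------------------------
# 2. chromosome localization
# ---------------------------------------------------------------------------

def chromosome_localization_score(
    region_count: float, region_length: int, chrom_density: float
) -> float:
    """Chi-squared (1 df) enrichment of the region against its chromosome.

    The expected breakpoint count is ``E = chrom_density * region_length``
    and the observed is the region's breakpoint count ``O``.  Regions at
    or below expectation score 0; enriched regions score the lower-tail
    probability of ``(O - E)^2 / E`` under a 1-df chi-squared law.
    """
    expected = chrom_density * region_length
    observed = float(region_count)
    if expected == 0.0:
        return 1.0 if observed > 0 else 0.0
    if observed <= expected:
        return 0.0
    chi2 = (observed - expected) ** 2 / expected
    return _clamp01(float(stats.chi2.cdf(chi2, df=1)))


# ---------------------------------------------------------------------------
# significance filter shared by the CNV and translocation hallmarks
# ---------------------------------------------------------------------------

def count_significant(values: Sequence[float], z_cutoff: float = -2.0) -> int:
    """Number of values whose z-score exceeds *z_cutoff*.

    Uses the population standard deviation.  When all values are equal
    (sd = 0) every value is significant; an empty input has none.
    """
    return int(significant_mask(values, z_cutoff).sum())


def significant_mask(values: Sequence[float], z_cutoff: float = -2.0) -> np.ndarray:
    """Boolean mask of values passing the z-score cutoff (see count_significant)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return np.zeros(0, dtype=bool)
    sd = arr.std()
    if sd == 0.0:
        return np.ones(arr.size, dtype=bool)
    return (arr - arr.mean()) / sd > z_cutoff


# ---------------------------------------------------------------------------
# 3. copy-number aberrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNStateTally:
    """Oscillation and segment counts per aberrant copy-number state.

    ``oscillations[s]`` counts the state transitions (into or out of
    state ``s``) along the chromosome; an isolated aberrant segment on
    the diploid baseline contributes two.  A transition directly
    between two different aberrant states counts once in each state's
    tally but once in ``total_oscillations``.
    """

    oscillations: dict[int, int]
    segment_counts: dict[int, int]
    total_oscillations: int

    @property
    def n_states(self) -> int:
        return len(self.oscillations)


def _resolve_overlaps(
    cnvs: Sequence[CNVCall], normal_cn: int
) -> list[tuple[int, int, int]]:
    """Disjoint, sorted aberrant segments as (start, end, state).

    Same-state overlaps are merged; where different states overlap the
    state further from the normal copy number claims the shared bases
    (ties break towards the higher state), with a logged warning.
    """
    by_state: dict[int, list[tuple[int, int]]] = {}
    for c in cnvs:
        if c.copy_number != normal_cn:
            by_state.setdefault(c.copy_number, []).append((c.start, c.end))
    merged = {s: intervals.merge(ivs) for s, ivs in by_state.items()}
    # amplitude priority: furthest from normal wins overlapping bases
    order = sorted(merged, key=lambda s: (abs(s - normal_cn), s), reverse=True)
    claimed: list[tuple[int, int]] = []
    segments: list[tuple[int, int, int]] = []
    for state in order:
        for iv in merged[state]:
            pieces = [iv]
            for c in claimed:
                pieces = [p for piece in pieces for p in intervals.subtract(piece, [c])]
            if pieces != [iv]:
                logger.warning(
                    "overlapping CNV segments near %s; state %d yields to a higher-amplitude state",
                    iv, state,
                )
            segments.extend((s, e, state) for s, e in pieces)
        claimed = intervals.merge(claimed + merged[state])
    segments.sort()
    return segments


def cn_oscillations(cnvs: Sequence[CNVCall], normal_cn: int = 2) -> CNStateTally:
    """Tally copy-number state oscillations over a diploid baseline.

    The CNV segments (all on one chromosome) are laid onto a
    normal-copy-number background; every boundary where the state
    changes is one oscillation.
    """
    segments = _resolve_overlaps(cnvs, normal_cn)
    osc: dict[int, int] = {}
    seg_counts: dict[int, int] = {}
    total = 0
    for i, (start, end, state) in enumerate(segments):
        seg_counts[state] = seg_counts.get(state, 0) + 1
        # left boundary: either an aberrant-aberrant transition shared with
        # the previous segment (one event, credited to both states) or a
        # normal-to-aberrant transition
        if i > 0 and segments[i - 1][1] + 1 == start:
            osc[state] = osc.get(state, 0) + 1
            prev_state = segments[i - 1][2]
            osc[prev_state] = osc.get(prev_state, 0) + 1
            total += 1
        else:
            osc[state] = osc.get(state, 0) + 1
            total += 1
        # right boundary back to normal, unless the next segment abuts (then
        # the shared event is counted at that segment's left boundary)
        if not (i + 1 < len(segments) and end + 1 == segments[i + 1][0]):
            osc[state] = osc.get(state, 0) + 1
            total += 1
    return CNStateTally(oscillations=osc, segment_counts=seg_counts, total_oscillations=total)


def cnv_score(tally: CNStateTally, z_cutoff: float = -2.0) -> float:
    """Score favouring few aberrant CN states with many oscillations.

    With ``N`` the number of significant states and ``x`` the mean
    number of oscillations per state halved
    (``sum(c_n) / (2 N)``), the score is
    ``(1/N) * (1 - 1 / (1 + log2(x)))`` clamped to [0, 1]; a region
    with no aberrant segments, or fewer oscillations than two per
    state (x <= 1), scores 0.
    """
    values = list(tally.oscillations.values())
    if not values:
        return 0.0
    mask = significant_mask(values, z_cutoff)
    n_sig = int(mask.sum())
    if n_sig == 0:
        return 0.0
    total = float(np.asarray(values, dtype=float)[mask].sum())
    x = total / (2.0 * n_sig)
    if x <= 1.0:
        return 0.0
    return _clamp01((1.0 / n_sig) * (1.0 - 1.0 / (1.0 + math.log2(x))))


# ---------------------------------------------------------------------------
# 4. translocation localization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartnerStats:
    """Translocation statistics for one partner chromosome of a region."""

    chrom: str
    count: int                     # translocations shared with the region
    breakpoints: tuple[int, ...]   # ordered breakpoints on the partner
    spread: float                  # mean adjacent separation after outlier removal
    expected_spread: float         # chromosome length / (breakpoints + 1)
    spread_factor: float           # log(1 + spread) - log(expected_spread)
    significant: bool


@dataclass(frozen=True)
class TranslocationResult:
    """Translocation-localization score with its two multiplicative terms."""

    score: float
    first_term: float
    second_term: float
    weighted_sum: float
    n_significant: int
    total_count: int               # c_T over significant partners
    partners: tuple[PartnerStats, ...] = ()


def translocation_spread(
    breakpoints: Sequence[int],
    expected_spread: float,
    outlier_z_cutoff: float = 2.0,
) -> float:
    """Mean separation of ordered breakpoints after dropping high outliers.

    Separations whose z-score exceeds *outlier_z_cutoff* are removed so
    that several tight breakpoint clusters separated by long gaps still
    register as clustered.  With fewer than two breakpoints there is no
    separation to measure and the expected spread is returned (neutral).
    """
    if len(breakpoints) < 2:
        return float(expected_spread)
    seps = np.diff(np.sort(np.asarray(breakpoints, dtype=float)))
    sd = seps.std()
    if sd > 0.0:
        keep = (seps - seps.mean()) / sd <= outlier_z_cutoff
        if keep.any():
            seps = seps[keep]
    return float(seps.mean())


def region_partner_breakpoints(
    region: MutatedRegion, translocations: Sequence[TranslocationCall] | None = None
) -> dict[str, tuple[int, list[int]]]:
    """Partner chromosomes of a region with their counts and breakpoints.

    For every translocation touching the region, the end that overlaps
    the region designates the *other* end's chromosome as a partner;
    that other end contributes its two delimiting breakpoints.  An
    intrachromosomal translocation with both ends in the region counts
    once per end on the shared chromosome.
    """
    if translocations is None:
        translocations = region.translocations
    partners: dict[str, tuple[int, list[int]]] = {}

    def add(partner: str, b1: int, b2: int) -> None:
        count, bps = partners.get(partner, (0, []))
        bps.extend((b1, b2))
        partners[partner] = (count + 1, bps)

    for t in translocations:
        src_in = t.src_chrom == region.chrom and intervals.overlaps(
            t.src_start, t.src_end, region.start, region.end
        )
        dst_in = t.dst_chrom == region.chrom and intervals.overlaps(
            t.dst_start, t.dst_end, region.start, region.end
        )
        if src_in:
            add(t.dst_chrom, t.dst_start, t.dst_end)
        if dst_in:
            add(t.src_chrom, t.src_start, t.src_end)
    return partners


def translocation_score(
    region: MutatedRegion,
    genome: GenomeModel,
    config: ScanConfig | None = None,
    translocations: Sequence[TranslocationCall] | None = None,
) -> TranslocationResult:
    """Score clustering of translocations between a region and few partners.

    The score is the product of two terms.  The first depends only on
    the number of partner chromosomes with significant translocation
    counts: 1 for a single partner, 0 beyond ``max_significant_partners``
    (default 8), and ``1 - 0.10 (N - 2)`` in between.  The second grows
    with the weighted sum ``sum_n (c_n^2 / c_T) * exp(-spread_factor_n)``
    over significant partners: each partner's squared count share is
    amplified when its breakpoints are tighter than the uniform
    expectation (spread factor < 0) and damped when looser.
    """
    config = config or ScanConfig()
    partners = region_partner_breakpoints(region, translocations)
    if not partners:
        return TranslocationResult(0.0, 0.0, 0.0, 0.0, 0, 0)

    names = sorted(partners, key=genome.order)
    counts = [partners[n][0] for n in names]
    mask = significant_mask(counts, config.significance_z_cutoff)
    n_sig = int(mask.sum())
    c_total = int(sum(c for c, m in zip(counts, mask) if m))

    stats_list: list[PartnerStats] = []
    weighted_sum = 0.0
    for name, count, sig in zip(names, counts, mask):
        bps = tuple(sorted(partners[name][1]))
        expected = genome.length(name) / (len(bps) + 1)
        spread = translocation_spread(bps, expected, config.outlier_z_cutoff)
        spread_factor = math.log(1.0 + spread) - math.log(expected)
        stats_list.append(PartnerStats(
            chrom=name, count=count, breakpoints=bps, spread=spread,
            expected_spread=expected, spread_factor=spread_factor, significant=bool(sig),
        ))
        if sig and c_total > 0:
            weighted_sum += (count ** 2 / c_total) * math.exp(-spread_factor)

    if n_sig > config.max_significant_partners:
        first = 0.0
    elif n_sig == 1:
        first = 1.0
    else:
        first = max(0.0, 1.0 - 0.10 * (n_sig - 2))

    if weighted_sum > 0.0:
        denom = math.log2(1.0 + weighted_sum)
        second = _clamp01(1.0 - 1.0 / denom) if denom > 0.0 else 0.0
    else:
        second = 0.0

    return TranslocationResult(
        score=_clamp01(first * second),
        first_term=first,
        second_term=second,
        weighted_sum=weighted_sum,
        n_significant=n_sig,
        total_count=c_total,
        partners=tuple(stats_list),
    )


# ---------------------------------------------------------------------------
# 5. retained heterozygosity
# ---------------------------------------------------------------------------

def heterozygosity_score(
    region_interval: tuple[int, int],
    cnv_intervals: Iterable[tuple[int, int]],
    loh_intervals: Iterable[tuple[int, int]],
) -> float:
    """Fraction of predicted-heterozygous bases not covered by LOH.

    The space between CNVs inside the region is assumed heterozygous;
    the score is one minus the fraction of that space overlapped by
    observed LOH segments.  If CNVs tile the whole region there is no
    prediction to test and the score is 0; with no LOH data nothing
    contradicts the prediction and the score is 1.
    """
    hetero = intervals.subtract(region_interval, cnv_intervals)
    denom = intervals.total_length(hetero)
    if denom == 0:
        return 0.0
    overlap = intervals.total_length(intervals.intersect(hetero, loh_intervals))
    return _clamp01(1.0 - overlap / denom)


# ---------------------------------------------------------------------------
# 6. short insertions at breakpoints
# ---------------------------------------------------------------------------

def region_translocation_breakpoints(region: MutatedRegion) -> list[int]:
    """Positions of translocation breakpoints that fall inside the region."""
    out: list[int] = []
    for t in region.translocations:
        if t.src_chrom == region.chrom:
            out.extend(p for p in (t.src_start, t.src_end) if region.start <= p <= region.end)
        if t.dst_chrom == region.chrom:
            out.extend(p for p in (t.dst_start, t.dst_end) if region.start <= p <= region.end)
    return out


def insertion_score(
    breakpoint_positions: Sequence[int],
    insertion_positions: Sequence[int],
    insertion_window: int = 10,
) -> float:
    """Fraction of breakpoints with a short insertion within the window.

    The distance test is inclusive: an insertion exactly
    ``insertion_window`` bp away counts, one base further does not.
    A region with no translocation breakpoints scores 0.
    """
    if not breakpoint_positions:
        return 0.0
    ins = np.sort(np.asarray(insertion_positions, dtype=np.int64))
    if ins.size == 0:
        return 0.0
    bps = np.asarray(breakpoint_positions, dtype=np.int64)
    # nearest insertion distance via binary search
    idx = np.searchsorted(ins, bps)
    left = np.where(idx > 0, np.abs(bps - ins[np.maximum(idx - 1, 0)]), np.iinfo(np.int64).max)
    right = np.where(idx < ins.size, np.abs(ins[np.minimum(idx, ins.size - 1)] - bps),
                     np.iinfo(np.int64).max)
    nearest = np.minimum(left, right)
    return float((nearest <= insertion_window).sum() / bps.size)


# ---------------------------------------------------------------------------
# 7. TP53
# ---------------------------------------------------------------------------

def tp53_score(user_flag: bool) -> float:
    """1 when the user asserts a non-synonymous TP53 mutation, else 0."""
    return 1.0 if user_flag else 0.0


def tp53_scan(
    translocations: Sequence[TranslocationCall],
    cnvs: Sequence[CNVCall],
    lohs: Sequence[LOHCall],
    insertions: Sequence[InsertionCall],
    tp53_interval: tuple[str, int, int],
    genome: GenomeModel,
) -> bool:
    """True when any SV or insertion overlaps the TP53 locus.

    This annotation is reported but never alters any score.
    """
    if tp53_interval[0] not in genome:
        return False
    chrom = genome.canonical(tp53_interval[0])
    start, end = int(tp53_interval[1]), int(tp53_interval[2])
    for t in translocations:
        if _ends_overlap(t, chrom, start, end):
            return True
    for c in cnvs:
        if c.chrom == chrom and intervals.overlaps(c.start, c.end, start, end):
            return True
    for l in lohs:
        if l.chrom == chrom and intervals.overlaps(l.start, l.end, start, end):
            return True
    for i in insertions:
        if i.chrom == chrom and start <= i.pos <= end:
            return True
    return False


def _ends_overlap(t: TranslocationCall, chrom: str, start: int, end: int) -> bool:
    return (t.src_chrom == chrom and intervals.overlaps(t.src_start, t.src_end, start, end)) or (
        t.dst_chrom == chrom and intervals.overlaps(t.dst_start, t.dst_end, start, end)
    )
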