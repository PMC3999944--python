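"""Combine hallmark scores into final chromothripsis calls.

The final score of a region is the weighted sum of its seven hallmark
sub-scores; with the default weights it lives in [0, 1] and values
above 0.37 mark a likely chromothriptic event.  All identified regions
are reported with their scores -- the threshold flags rather than
filters, so the background distribution stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import density_scan, hallmark_scores
from .density_scan import Breakpoint, DensityStats, MutatedRegion, WindowScan
from .hallmark_scores import CNStateTally, HallmarkScores, TranslocationResult
from .io_formats import (
    CNVCall,
    GenomeModel,
    HALLMARK_NAMES,
    InsertionCall,
    LOHCall,
    ScanConfig,
    TranslocationCall,
    WeightConfig,
)

__all__ = ["ChromothripsisCall", "PipelineResult", "combine", "run_pipeline", "score_sample"]


@dataclass
class ChromothripsisCall:
    """A scored highly mutated region: the unit of the final report."""

    region: MutatedRegion
    hallmarks: HallmarkScores
    final_score: float
    exceeds_threshold: bool
    tp53_annotation: bool
    cn_tally: CNStateTally
    translocation: TranslocationResult
    support: dict


@dataclass
class PipelineResult:
    """Everything the pipeline computes, ready for reporting."""

    calls: list[ChromothripsisCall]
    density_stats: DensityStats
    window_scan: WindowScan
    per_chromosome_cn: dict[str, CNStateTally]
    translocation_matrix: pd.DataFrame   # directed: row = source, column = destination
    tp53_discovered: bool
    genome: GenomeModel
    weights: WeightConfig
    scan_config: ScanConfig


def combine(hallmarks: HallmarkScores, weights: WeightConfig) -> float:
    """Weighted sum of the seven hallmark scores."""
    d = hallmarks.as_dict()
    w = weights.as_dict()
    return sum(w[name] * d[name] for name in HALLMARK_NAMES)


def _score_region(
    region: MutatedRegion,
    stats: DensityStats,
    genome: GenomeModel,
    config: ScanConfig,
    tp53_mutated: bool,
) -> tuple[HallmarkScores, CNStateTally, TranslocationResult, dict]:
    chrom_density = stats.densities[region.chrom]

    g_score = hallmark_scores.genome_localization_score(chrom_density, stats.mean, stats.sd)
    c_score = hallmark_scores.chromosome_localization_score(
        region.breakpoint_count, region.length, chrom_density
    )

    tally = hallmark_scores.cn_oscillations(region.cnvs, config.normal_copy_number)
    cnv = hallmark_scores.cnv_score(tally, config.significance_z_cutoff)

    transloc = hallmark_scores.translocation_score(region, genome, config)

    het = hallmark_scores.heterozygosity_score(
        (region.start, region.end),
        [(c.start, c.end) for c in region.cnvs],
        [(l.start, l.end) for l in region.lohs],
    )

    bp_positions = hallmark_scores.region_translocation_breakpoints(region)
    ins = hallmark_scores.insertion_score(
        bp_positions,
        [i.pos for i in region.insertions],
        config.insertion_window,
    )

    hallmarks = HallmarkScores(
        genome_localization=g_score,
        chromosome_localization=c_score,
        cnv=cnv,
        translocation=transloc.score,
        heterozygosity=het,
        insertion=ins,
        tp53=hallmark_scores.tp53_score(tp53_mutated),
    )
    support = {
        "chromosome_density": chrom_density,
        "genome_density_mean": stats.mean,
        "genome_density_sd": stats.sd,
        "breakpoint_count": region.breakpoint_count,
        "region_density": region.region_density,
        "expected_breakpoints": chrom_density * region.length,
        "n_aberrant_cn_states": tally.n_states,
        "cn_oscillations": tally.total_oscillations,
        "n_translocations": len(region.translocations),
        "n_significant_partners": transloc.n_significant,
        "translocation_weighted_sum": transloc.weighted_sum,
        "translocation_first_term": transloc.first_term,
        "translocation_second_term": transloc.second_term,
        "n_region_breakpoints_tested": len(bp_positions),
        "n_insertions": len(region.insertions),
        "n_loh_segments": len(region.lohs),
    }
    return hallmarks, tally, transloc, support


def run_pipeline(
    translocations: Sequence[TranslocationCall] | None,
    cnvs: Sequence[CNVCall] | None,
    lohs: Sequence[LOHCall] | None = None,
    insertions: Sequence[InsertionCall] | None = None,
    *,
    genome: GenomeModel,
    weights: WeightConfig | None = None,
    scan_config: ScanConfig | None = None,
    tp53_mutated: bool = False,
) -> PipelineResult:
    """Run the full analysis: breakpoints, densities, windows, region scores.

    Translocation and CNV inputs are mandatory (pass empty lists for a
    sample with no such calls); LOH and insertion inputs are optional
    and default to absent.
    """
    if translocations is None or cnvs is None:
        raise ValueError("translocation and CNV calls are both required inputs")
    weights = weights or WeightConfig()
    config = scan_config or ScanConfig()
    lohs = list(lohs or [])
    insertions = list(insertions or [])

    bps = density_scan.extract_breakpoints(translocations, cnvs, genome)
    stats = density_scan.chromosome_densities(bps, genome)
    scan = density_scan.sliding_window_scan(bps, genome, config)
    regions = density_scan.identify_mutated_regions(
        scan, genome, config, translocations, cnvs, lohs, insertions, bps
    )
    tp53_found = hallmark_scores.tp53_scan(
        translocations, cnvs, lohs, insertions, config.tp53_interval, genome
    )

    calls: list[ChromothripsisCall] = []
    for region in regions:
        hm, tally, transloc, support = _score_region(region, stats, genome, config, tp53_mutated)
        final = combine(hm, weights)
        calls.append(ChromothripsisCall(
            region=region,
            hallmarks=hm,
            final_score=final,
            exceeds_threshold=final > config.call_threshold,
            tp53_annotation=tp53_found,
            cn_tally=tally,
            translocation=transloc,
            support=support,
        ))
    calls.sort(key=lambda c: (-c.final_score, genome.order(c.region.chrom), c.region.start))

    per_chrom_cn = {
        name: hallmark_scores.cn_oscillations(
            [c for c in cnvs if c.chrom == name], config.normal_copy_number
        )
        for name in genome.names
    }
    matrix = pd.DataFrame(0, index=list(genome.names), columns=list(genome.names), dtype=int)
    for t in translocations:
        matrix.loc[t.src_chrom, t.dst_chrom] += 1

    return PipelineResult(
        calls=calls,
        density_stats=stats,
        window_scan=scan,
        per_chromosome_cn=per_chrom_cn,
        translocation_matrix=matrix,
        tp53_discovered=tp53_found,
        genome=genome,
        weights=weights,
        scan_config=config,
    )


def score_sample(
    translocations: Sequence[TranslocationCall] | None,
    cnvs: Sequence[CNVCall] | None,
    lohs: Sequence[LOHCall] | None = None,
    insertions: Sequence[InsertionCall] | None = None,
    *,
    genome: GenomeModel,
    weights: WeightConfig | None = None,
    scan_config: ScanConfig | None = None,
    tp53_mutated: bool = False,
) -> list[ChromothripsisCall]:
    """Score a sample and return its calls sorted by final score, descending."""
    return run_pipeline(
        translocations, cnvs, lohs, insertions,
        genome=genome, weights=weights, scan_config=scan_config, tp53_mutated=tp53_mutated,
    ).calls
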