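"""Final YAML report and tab-delimited intermediate files.

The final report is machine-parseable YAML: run metadata, the effective
configuration, and one entry per suspect region ordered by score.  All
floating-point values are serialized with six decimals so repeated runs
on identical inputs produce byte-identical files.

Five intermediate TSVs expose the raw statistics behind the scores:
sliding-window counts, per-chromosome SV density, per-chromosome CN
oscillations, per-chromosome aberrant-state counts, and the directed
translocation count matrix (rows = source, columns = destination).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .aggregate_scoring import ChromothripsisCall, PipelineResult

__all__ = ["write_final_report", "write_intermediates", "INTERMEDIATE_FILES"]

INTERMEDIATE_FILES = (
    "sliding_window.tsv",
    "sv_density.tsv",
    "cn_oscillations.tsv",
    "aberrant_cn_states.tsv",
    "translocation_counts.tsv",
)


def _r6(x: float) -> float:
    return round(float(x), 6)


def _call_entry(call: ChromothripsisCall) -> dict:
    region = call.region
    return {
        "chromosome": region.chrom,
        "start": int(region.start),
        "end": int(region.end),
        "chromothripsis_score": _r6(call.final_score),
        "exceeds_call_threshold": bool(call.exceeds_threshold),
        "tp53_mutation_discovered": bool(call.tp53_annotation),
        "hallmark_scores": {k: _r6(v) for k, v in call.hallmarks.as_dict().items()},
        "statistics": {
            k: (_r6(v) if isinstance(v, float) else int(v)) for k, v in call.support.items()
        },
    }


def write_final_report(
    calls: Sequence[ChromothripsisCall],
    path: str | Path,
    *,
    weights=None,
    scan_config=None,
    inputs: dict | None = None,
) -> None:
    """Write the YAML final report for *calls* (already sorted by score)."""
    from . import __version__

    tp53_found = any(c.tp53_annotation for c in calls)
    doc = {
        "tool": "shatterscan",
        "version": __version__,
        "n_suspect_regions": len(calls),
        "tp53_mutation_discovered": bool(tp53_found),
    }
    if inputs:
        doc["inputs"] = {k: str(v) for k, v in inputs.items()}
    config: dict = {}
    if weights is not None:
        config["weights"] = {k: _r6(v) for k, v in weights.as_dict().items()}
    if scan_config is not None:
        config["scan"] = scan_config.as_dict()
    if config:
        doc["config"] = config
    doc["suspect_regions"] = [_call_entry(c) for c in calls]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, default_flow_style=False)


def write_intermediates(result: PipelineResult, outdir: str | Path) -> dict[str, Path]:
    """Write the five intermediate TSV tables; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    windows = result.window_scan.frame()
    paths["sliding_window.tsv"] = outdir / "sliding_window.tsv"
    windows.to_csv(paths["sliding_window.tsv"], sep="\t", index=False)

    density = result.density_stats.frame()
    density["length"] = [result.genome.length(c) for c in density["chromosome"]]
    density["density"] = density["density"].map(lambda x: f"{x:.6e}")
    paths["sv_density.tsv"] = outdir / "sv_density.tsv"
    density[["chromosome", "length", "breakpoints", "density"]].to_csv(
        paths["sv_density.tsv"], sep="\t", index=False
    )

    osc = pd.DataFrame({
        "chromosome": list(result.per_chromosome_cn),
        "cn_state_oscillations": [t.total_oscillations for t in result.per_chromosome_cn.values()],
    })
    paths["cn_oscillations.tsv"] = outdir / "cn_oscillations.tsv"
    osc.to_csv(paths["cn_oscillations.tsv"], sep="\t", index=False)

    states = pd.DataFrame({
        "chromosome": list(result.per_chromosome_cn),
        "n_aberrant_cn_states": [t.n_states for t in result.per_chromosome_cn.values()],
    })
    paths["aberrant_cn_states.tsv"] = outdir / "aberrant_cn_states.tsv"
    states.to_csv(paths["aberrant_cn_states.tsv"], sep="\t", index=False)

    paths["translocation_counts.tsv"] = outdir / "translocation_counts.tsv"
    result.translocation_matrix.to_csv(
        paths["translocation_counts.tsv"], sep="\t", index_label="source"
    )
    return paths
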