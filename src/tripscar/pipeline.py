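"""In-memory orchestration of the full analysis chain.

The CLI drives the same stages through files; this module wires them
directly for programmatic use (simulation studies, validation runs).
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .cluster import cluster_barcodes, counts_from_results
from .config import PipelineParams, ReporterSpec
from .extract import extract_reads
from .mapping import aggregate_locations, filter_locations, resolve_softclips
from .pathway import classify_pathways, estimate_cells, filter_not_clear, summarize_pool
from .scars import call_reads
from .simulate import naive_align


def analyze_experiment(
    exp: dict,
    params: Optional[PipelineParams] = None,
    scar_mode: str = "count",
    min_cells_filter: bool = False,
) -> dict:
    """Run extraction, clustering, mapping, scar calling and quantification
    on a simulated experiment (the dict from ``simulate_experiment``).

    Returns a dict with: results, stats, cluster_table, mapping_table,
    integration_calls, counts, details, pathway, joined.
    """
    spec: ReporterSpec = exp["spec"]
    params = params or PipelineParams()

    results, stats = extract_reads(
        exp["indel_reads"], spec, params, index_table=exp["index_table"]
    )
    ok = [r for r in results if r.ok]
    cluster_table = cluster_barcodes(
        counts_from_results(r.barcode for r in ok), params.max_barcode_dist
    )

    ipcr = exp["ipcr"]
    genome = ipcr["genome"]
    reads2 = resolve_softclips(ipcr["r2"], lambda s: naive_align(s, genome))
    mapping_table = aggregate_locations(reads2)
    integration_calls = filter_locations(mapping_table, params)

    counts, details = call_reads(ok, spec, mode=scar_mode)
    counts = filter_not_clear(counts)
    genuine = set(cluster_table["genuine_barcode"])
    counts = counts[counts["barcode"].isin(genuine)].reset_index(drop=True)
    if min_cells_filter:
        cells = estimate_cells(counts, params)
        kept = set(cells.loc[cells["kept"], "barcode"])
        counts = counts[counts["barcode"].isin(kept)].reset_index(drop=True)
    pathway = classify_pathways(counts, details=details)
    joined = summarize_pool(pathway, integration_calls)
    return {
        "results": results,
        "stats": stats,
        "cluster_table": cluster_table,
        "mapping_table": mapping_table,
        "integration_calls": integration_calls,
        "counts": counts,
        "details": details,
        "pathway": pathway,
        "joined": joined,
    }
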