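"""Levenshtein clustering of observed barcodes into genuine/mutated classes.

Sequencing and PCR errors scatter each true ("genuine") barcode into a cloud
of low-abundance mutated neighbours. Greedy sphere clustering resolves them:
candidate centers are processed by descending count (ties broken
lexicographically, so runs are deterministic), and every unassigned barcode
within the Levenshtein radius of the current center joins its cluster. The
radius default is 1, i.e. distance < 2. Length-15/17 barcodes cluster with
16-mers naturally, since Levenshtein distance handles length differences.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import edlib
import pandas as pd

log = logging.getLogger(__name__)

CLUSTER_COLUMNS = ["member_barcode", "genuine_barcode", "cluster_total"]


def levenshtein(a: str, b: str) -> int:
    """Standard unit-cost edit distance (substitution, insertion, deletion)."""
    return edlib.align(a, b, task="distance")["editDistance"]


def _within(a: str, b: str, max_dist: int) -> bool:
    # edlib's banded mode returns -1 when the distance exceeds k
    return edlib.align(a, b, task="distance", k=max_dist)["editDistance"] != -1


def cluster_barcodes(counts: Mapping[str, int], max_dist: int = 1) -> pd.DataFrame:
    """Greedy sphere clustering of barcode counts.

    Parameters
    ----------
    counts : mapping barcode -> observed read count (all >= 1, non-empty).
    max_dist : Levenshtein radius; members join a center at distance <= max_dist.

    Returns
    -------
    DataFrame with columns member_barcode, genuine_barcode, cluster_total.
    The center (most abundant barcode, ties lexicographic) is the genuine
    barcode; cluster_total is the summed member count, identical on every
    row of the cluster. Sum of per-cluster totals equals the input total.
    """
    if not counts:
        raise ValueError("cluster_barcodes: empty barcode count table")
    if any(c < 1 for c in counts.values()):
        raise ValueError("cluster_barcodes: all counts must be >= 1")
    order = sorted(counts, key=lambda b: (-counts[b], b))
    assigned: dict[str, str] = {}
    clusters: dict[str, list[str]] = {}
    for center in order:
        if center in assigned:
            continue
        members = [center]
        assigned[center] = center
        for other in order:
            if other in assigned:
                continue
            if _within(center, other, max_dist):
                assigned[other] = center
                members.append(other)
        clusters[center] = members
    rows = []
    for center, members in clusters.items():
        total = sum(counts[m] for m in members)
        for m in members:
            rows.append((m, center, total))
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


def apply_clusters(
    table: pd.DataFrame, records: pd.DataFrame, mode: str = "filter"
) -> tuple[pd.DataFrame, int]:
    """Filter or rescue barcode-keyed rows using a cluster table.

    mode="filter": rows whose barcode is not a genuine barcode are dropped.
    mode="rescue": each row's barcode is rewritten to its cluster's genuine
    barcode and, when a ``reads`` column is present, rows collapsing onto the
    same key are merged by summing reads.

    Rows whose barcode is absent from the cluster table are dropped and
    counted (second return value), never an error.
    """
    if mode not in ("filter", "rescue"):
        raise ValueError(f"unknown mode {mode!r}")
    genuine = set(table["genuine_barcode"])
    if mode == "filter":
        keep = records["barcode"].isin(genuine)
        dropped = int((~keep).sum())
        return records[keep].reset_index(drop=True), dropped
    mapping = dict(zip(table["member_barcode"], table["genuine_barcode"]))
    known = records["barcode"].isin(mapping)
    dropped = int((~known).sum())
    if dropped:
        log.info("apply_clusters: %d rows with unclustered barcodes dropped", dropped)
    out = records[known].copy()
    out["barcode"] = out["barcode"].map(mapping)
    if "reads" in out.columns:
        keys = [c for c in out.columns if c != "reads"]
        out = out.groupby(keys, dropna=False, as_index=False)["reads"].sum()
    return out.reset_index(drop=True), dropped


def counts_from_results(barcodes: Iterable[str]) -> dict[str, int]:
    """Tally observed barcodes (e.g. from ExtractionResults) into counts."""
    counts: dict[str, int] = {}
    for b in barcodes:
        if b:
            counts[b] = counts.get(b, 0) + 1
    return counts


def write_cluster_table(table: pd.DataFrame, path: str) -> None:
    """Write the three-column member/genuine/total TSV."""
    table.to_csv(path, sep="\t", index=False)
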