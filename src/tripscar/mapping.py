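"""Per-barcode integration-site calling from iPCR alignments.

Inverse PCR circularises a genomic fragment around each integrated reporter;
the mate reading from the transposon edge into the genome (read 2) locates
the integration. Circular ligation can splice a distant locus into the
fragment, which shows up as a leading soft-clip at the read's 5' end: short
clips are discarded, clips > 16 bp are realigned so the sequence truly
adjacent to the reporter is the one that counts. Surviving reads are
aggregated per barcode into the top-2 supported locations, then filtered on
read support, average MAPQ and primary/secondary read fractions.

Alignment itself is delegated (SAM is consumed); genomic coordinates are
0-based internally and 1-based only in exported TSV.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import pandas as pd

from .config import PipelineParams

log = logging.getLogger(__name__)

SOFTCLIP_REALIGN_THRESHOLD = 16  # bp; > this, the clipped sequence is realigned

#: reads whose 5'-most positions differ by no more than this collapse into
#: one location group (absorbs end-trimming jitter)
POSITION_COLLAPSE_WINDOW = 2

FILTER_REASONS = ("min_reads", "min_avg_mapq", "min_primary_frac", "max_secondary_frac")


@dataclass
class AlignedRead:
    """One aligned iPCR mate with the barcode already resolved.

    ``pos`` is the 0-based leftmost aligned reference base; ``five_prime_pos``
    gives the transposon-adjacent (5' in read orientation) genomic base used
    as the location key.
    """

    barcode: str
    mate: str  # "r1" | "r2"
    chrom: str
    pos: int
    strand: str  # "+" | "-"
    mapq: int
    leading_softclip_len: int = 0
    clipped_seq: Optional[str] = None
    ref_len: int = 0

    @property
    def five_prime_pos(self) -> int:
        if self.strand == "+":
            return self.pos
        return self.pos + max(self.ref_len, 1) - 1


def triage_softclip(read: AlignedRead, threshold: int = SOFTCLIP_REALIGN_THRESHOLD):
    """Decide what to do with a transposon-edge mate based on its 5' clip.

    Returns "keep" (no clip), "discard" (clip of 1..threshold bp), or
    ("realign", clipped_seq) for clips longer than threshold.
    """
    n = read.leading_softclip_len
    if n == 0:
        return "keep"
    if n <= threshold:
        return "discard"
    if read.clipped_seq is None:
        raise ValueError(
            f"read with {n} bp leading soft-clip has no clipped sequence to realign"
        )
    return ("realign", read.clipped_seq)


def resolve_softclips(
    reads: Iterable[AlignedRead],
    realigner: Optional[Callable[[str], Optional[tuple[str, int, str, int]]]] = None,
    threshold: int = SOFTCLIP_REALIGN_THRESHOLD,
) -> list[AlignedRead]:
    """Apply soft-clip triage; realigned clips re-enter as ordinary reads.

    ``realigner(seq)`` maps a clipped sequence to (chrom, pos, strand,
    ref_len) or None; e.g. :func:`tripscar.simulate.naive_align` bound to a
    mini-genome. Without a realigner, clips > threshold are dropped.
    """
    out: list[AlignedRead] = []
    n_discard = n_realigned = n_lost = 0
    for read in reads:
        verdict = triage_softclip(read, threshold)
        if verdict == "keep":
            out.append(read)
        elif verdict == "discard":
            n_discard += 1
        else:
            _, seq = verdict
            hit = realigner(seq) if realigner is not None else None
            if hit is None:
                n_lost += 1
                continue
            chrom, pos, strand, ref_len = hit
            out.append(
                AlignedRead(
                    barcode=read.barcode,
                    mate=read.mate,
                    chrom=chrom,
                    pos=pos,
                    strand=strand,
                    mapq=read.mapq,
                    ref_len=ref_len,
                )
            )
            n_realigned += 1
    log.info(
        "soft-clip triage: %d kept, %d discarded, %d realigned, %d unresolved",
        len(out) - n_realigned, n_discard, n_realigned, n_lost,
    )
    return out


def _group_positions(entries: list[tuple[int, int]]) -> list[tuple[int, int, float]]:
    """Collapse (pos, mapq) entries within the position window.

    Returns (representative_pos, n_reads, mapq_sum) per group; the
    representative is the modal position (ties -> smallest).
    """
    entries = sorted(entries)
    groups: list[tuple[int, int, float]] = []
    i = 0
    while i < len(entries):
        anchor = entries[i][0]
        j = i
        while j < len(entries) and entries[j][0] - anchor <= POSITION_COLLAPSE_WINDOW:
            j += 1
        chunk = entries[i:j]
        freq: dict[int, int] = defaultdict(int)
        for p, _ in chunk:
            freq[p] += 1
        rep = min(freq, key=lambda p: (-freq[p], p))
        groups.append((rep, len(chunk), float(sum(q for _, q in chunk))))
        i = j
    return groups


def aggregate_locations(reads: Iterable[AlignedRead]) -> pd.DataFrame:
    """Per-barcode top-2 location groups with read counts and MAPQ sums.

    Reads are grouped by barcode and by (chrom, strand, position within the
    collapse window); the two groups with the most reads are reported. Ties
    break deterministically by (count desc, mapq_sum desc, chrom, pos).
    """
    per_bc: dict[str, dict[tuple[str, str], list[tuple[int, int]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for r in reads:
        per_bc[r.barcode][(r.chrom, r.strand)].append((r.five_prime_pos, r.mapq))
    rows = []
    for barcode in sorted(per_bc):
        locs: list[tuple[str, int, str, int, float]] = []
        total = 0
        for (chrom, strand), entries in per_bc[barcode].items():
            for pos, n, qsum in _group_positions(entries):
                locs.append((chrom, pos, strand, n, qsum))
                total += n
        locs.sort(key=lambda t: (-t[3], -t[4], t[0], t[1]))
        c1, p1, s1, n1, q1 = locs[0]
        row = {
            "barcode": barcode,
            "chrom1": c1, "pos1": p1, "strand1": s1, "reads1": n1, "mapq_sum1": q1,
            "chrom2": None, "pos2": None, "strand2": None, "reads2": 0, "mapq_sum2": 0.0,
            "total_reads": total,
        }
        if len(locs) > 1:
            c2, p2, s2, n2, q2 = locs[1]
            row.update(chrom2=c2, pos2=p2, strand2=s2, reads2=n2, mapq_sum2=q2)
        rows.append(row)
    return pd.DataFrame(rows)


def filter_locations(table: pd.DataFrame, params: PipelineParams) -> pd.DataFrame:
    """Apply the four trustworthy-integration predicates to a mapping table.

    A barcode passes iff reads1 >= min_ipcr_reads, average primary MAPQ
    > min_avg_mapq, the primary location holds >= min_primary_frac of the
    barcode's reads, and a secondary location holds <= max_secondary_frac.
    Failures carry every violated reason, comma-joined.
    """
    rows = []
    for rec in table.itertuples(index=False):
        reasons = []
        if rec.reads1 < params.min_ipcr_reads:
            reasons.append("min_reads")
        if rec.reads1 <= 0 or rec.mapq_sum1 / rec.reads1 <= params.min_avg_mapq:
            reasons.append("min_avg_mapq")
        total = rec.total_reads
        if total <= 0 or rec.reads1 / total < params.min_primary_frac:
            reasons.append("min_primary_frac")
        if total > 0 and rec.reads2 / total > params.max_secondary_frac:
            reasons.append("max_secondary_frac")
        rows.append(
            {
                "barcode": rec.barcode,
                "chrom": rec.chrom1,
                "pos": rec.pos1,
                "strand": rec.strand1,
                "status": "pass" if not reasons else "fail",
                "reasons": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows)


def read_sam(
    path: str,
    mate: str = "r2",
    barcode_from: str = "tag",
    tag: str = "BC",
) -> list[AlignedRead]:
    """Load aligned reads from SAM/BAM with their barcodes.

    ``barcode_from="tag"`` reads the barcode from a SAM tag (default ``BC``);
    ``barcode_from="name"`` parses a ``BC=<seq>`` field from the underscore-
    separated read name. Unmapped records are skipped.
    """
    import pysam

    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if barcode_from == "tag":
                barcode = rec.get_tag(tag)
            else:
                fields = dict(
                    f.split("=", 1) for f in rec.query_name.split("_") if "=" in f
                )
                barcode = fields.get("BC", "")
            strand = "-" if rec.is_reverse else "+"
            cigar = rec.cigartuples or []
            # leading soft clip at the read's 5' end: first op on +, last on -
            clip_op = cigar[0] if strand == "+" else (cigar[-1] if cigar else None)
            clip_len = clip_op[1] if clip_op and clip_op[0] == 4 else 0
            clipped_seq = None
            if clip_len and rec.query_sequence:
                seq = rec.query_sequence
                clipped_seq = seq[:clip_len] if strand == "+" else seq[-clip_len:]
            reads.append(
                AlignedRead(
                    barcode=barcode,
                    mate=mate,
                    chrom=rec.reference_name,
                    pos=rec.reference_start,
                    strand=strand,
                    mapq=rec.mapping_quality,
                    leading_softclip_len=clip_len,
                    clipped_seq=clipped_seq,
                    ref_len=rec.reference_length or 0,
                )
            )
    return reads


def write_mapping_table(
    table: pd.DataFrame, calls: pd.DataFrame, path: str
) -> None:
    """Export a mapping table + filter verdicts as TSV (1-based starts)."""
    out = table.merge(calls[["barcode", "status", "reasons"]], on="barcode")
    out = out.copy()
    out["start_1based"] = out["pos1"] + 1
    out.to_csv(path, sep="\t", index=False)
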