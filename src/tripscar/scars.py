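"""Repair-scar calling for indel-PCR reads.

Each adapter-trimmed read remainder is tested for two signals:

1. *Recognition sequences* — exact named sequences (the wild-type scar
   region, plus optionally designed products such as an SSTR insertion).
   A hit names the call ("wt" or the configured name).
2. *Spacer shift* — seven 6-mer marker sequences sit downstream of the cut
   at known wild-type offsets; the positional shift of the first spacer
   found (occurrence nearest its expected offset) is the indel size. This is
   robust to sequencing errors and mutations downstream of the first intact
   spacer, and captures the full deletion-size range the PCR can span.

Without a recognition hit the indel size drives the call: "del" (< 0),
"ins" (> 0) or "wt_point_mut" (0). With neither signal the call is
"not_clear". The indel size is attached even when a recognition sequence is
found, so a "wt" call can legitimately carry a nonzero size (mutation
outside the targeted region). An optional pairwise-alignment mode resolves
the exact scar — deletion interval, inserted sequence and flanking
microhomology — at extra compute cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from Bio import Align

from ._seq import find_all
from .config import ReporterSpec

log = logging.getLogger(__name__)

CALLS = ("wt", "del", "ins", "wt_point_mut", "not_clear")

# pairwise scar alignment scoring (module defaults, overridable)
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0
MIN_ALIGN_IDENTITY = 0.5


@dataclass
class MutationCall:
    call: str
    indel_size: Optional[int]


@dataclass
class ScarDetail:
    """Exact scar from pairwise alignment.

    ``deletion`` is a half-open interval in wt_amplicon coordinates
    (left-aligned: shifted maximally toward the 5' end, the convention under
    which MMEJ coordinate ambiguity equals flanking-repeat length).
    ``microhomology_len`` is the number of bases the deletion can slide
    right, i.e. the flanking direct-repeat length.
    """

    deletion: Optional[tuple[int, int]] = None
    insertion: Optional[str] = None
    microhomology_len: int = 0
    net_size: int = 0


def match_recognition(remainder: str, spec: ReporterSpec) -> Optional[str]:
    """Name of the longest recognition sequence found verbatim, or None.

    Matching is exact: recognition sequences define calls, and the taxonomy
    already routes mismatched reads to size-based calls.
    """
    best: Optional[str] = None
    best_len = -1
    for name in sorted(spec.recognition_seqs):
        seq = spec.recognition_seqs[name]
        if seq in remainder and len(seq) > best_len:
            best, best_len = name, len(seq)
    return best


def indel_size_by_spacers(remainder: str, spec: ReporterSpec) -> Optional[int]:
    """Indel size from the positional shift of the first spacer found.

    Spacers are scanned in order; for the first one present, the occurrence
    nearest its expected offset is used (a spacer sequence can reappear by
    chance after mutation) and observed - expected is returned. None when no
    spacer is found.
    """
    sizes = []
    for seq, expected in spec.spacers:
        occ = find_all(remainder, seq)
        if occ:
            obs = min(occ, key=lambda o: (abs(o - expected), o))
            sizes.append(obs - expected)
    if not sizes:
        return None
    if len(set(sizes)) > 1:
        log.debug("spacer disagreement: shifts %s", sizes)
    return sizes[0]


def classify_read(remainder: str, spec: ReporterSpec) -> MutationCall:
    """Full call taxonomy for one read remainder; total — never raises."""
    name = match_recognition(remainder, spec)
    size = indel_size_by_spacers(remainder, spec)
    if name is not None:
        return MutationCall(name, size)
    if size is None:
        return MutationCall("not_clear", None)
    if size < 0:
        return MutationCall("del", size)
    if size > 0:
        return MutationCall("ins", size)
    return MutationCall("wt_point_mut", 0)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    # reads are right-truncated at the sequencer's read length, so overhang
    # past either sequence's right end is free, not a deletion
    for new, old in (
        ("open_right_insertion_score", "target_right_open_gap_score"),
        ("extend_right_insertion_score", "target_right_extend_gap_score"),
        ("open_right_deletion_score", "query_right_open_gap_score"),
        ("extend_right_deletion_score", "query_right_extend_gap_score"),
    ):
        try:
            setattr(aligner, new, 0.0)
        except AttributeError:
            setattr(aligner, old, 0.0)
    return aligner


_ALIGNER: Optional[Align.PairwiseAligner] = None


def align_scar(remainder: str, spec: ReporterSpec) -> Optional[ScarDetail]:
    """Exact scar from global pairwise alignment against the wild type.

    Deletions are left-aligned before the microhomology is measured. Returns
    None (read falls back to not_clear) when alignment identity over the
    aligned columns drops below MIN_ALIGN_IDENTITY.
    """
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _make_aligner()
    wt = spec.wt_amplicon
    if not remainder:
        return None
    aln = _ALIGNER.align(wt, remainder)[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    matches = 0
    columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        columns += te - ts
        matches += sum(wt[ts + i] == remainder[qs + i] for i in range(te - ts))
    # internal gaps count as alignment columns too
    for k in range(1, len(t_blocks)):
        columns += t_blocks[k][0] - t_blocks[k - 1][1]  # deletion length
        columns += q_blocks[k][0] - q_blocks[k - 1][1]  # insertion length
    if columns == 0 or matches / columns < MIN_ALIGN_IDENTITY:
        return None

    deletions: list[tuple[int, int]] = []
    insertion: Optional[str] = None
    ins_len = 0
    for k in range(1, len(t_blocks)):
        d = t_blocks[k][0] - t_blocks[k - 1][1]
        if d > 0:
            deletions.append((t_blocks[k - 1][1], t_blocks[k][0]))
        i = q_blocks[k][0] - q_blocks[k - 1][1]
        if i > 0:
            seg = remainder[q_blocks[k - 1][1] : q_blocks[k][0]]
            if insertion is None or len(seg) > len(insertion):
                insertion = seg
            ins_len += i

    detail = ScarDetail(net_size=ins_len - sum(e - s for s, e in deletions))
    detail.insertion = insertion
    if deletions:
        # report the largest deletion, left-aligned
        start, end = max(deletions, key=lambda d: d[1] - d[0])
        while start > 0 and wt[start - 1] == wt[end - 1]:
            start -= 1
            end -= 1
        mh = 0
        while end + mh < len(wt) and wt[start + mh] == wt[end + mh]:
            mh += 1
        detail.deletion = (start, end)
        detail.microhomology_len = mh
    return detail


def count_scars(calls: Iterable[tuple[str, MutationCall]]) -> pd.DataFrame:
    """Group (barcode, call) pairs into the four-column ".count" table.

    Columns: barcode, call, indel_size (nullable Int64), reads. Rows are
    sorted by (barcode, call, indel_size) for deterministic output.
    """
    tally: dict[tuple[str, str, Optional[int]], int] = {}
    for barcode, mc in calls:
        key = (barcode, mc.call, mc.indel_size)
        tally[key] = tally.get(key, 0) + 1
    rows = [
        {"barcode": b, "call": c, "indel_size": s, "reads": n}
        for (b, c, s), n in tally.items()
    ]
    df = pd.DataFrame(rows, columns=["barcode", "call", "indel_size", "reads"])
    df["indel_size"] = df["indel_size"].astype("Int64")
    return df.sort_values(
        ["barcode", "call", "indel_size"], na_position="last"
    ).reset_index(drop=True)


def call_reads(
    results: Iterable, spec: ReporterSpec, mode: str = "count"
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Call every successfully extracted read; returns (.count table, details).

    ``results`` are ExtractionResults; failed extractions are skipped (they
    were already counted by the extraction stats). mode="align" additionally
    runs the pairwise-alignment scar analysis and returns a detail table
    with deletion interval, inserted sequence and microhomology length.
    """
    calls: list[tuple[str, MutationCall]] = []
    detail_rows: list[dict] = []
    for res in results:
        if not res.ok:
            continue
        mc = classify_read(res.remainder, spec)
        if mode == "align":
            det = align_scar(res.remainder, spec)
            if det is None and mc.call not in ("wt",):
                mc = MutationCall("not_clear", None)
            detail_rows.append(
                {
                    "read_id": res.read_id,
                    "barcode": res.barcode,
                    "call": mc.call,
                    "indel_size": mc.indel_size,
                    "del_start": det.deletion[0] if det and det.deletion else None,
                    "del_end": det.deletion[1] if det and det.deletion else None,
                    "insertion": det.insertion if det else None,
                    "microhomology_len": det.microhomology_len if det else None,
                    "net_size": det.net_size if det else None,
                }
            )
        calls.append((res.barcode, mc))
    counts = count_scars(calls)
    details = pd.DataFrame(detail_rows) if mode == "align" else None
    return counts, details
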