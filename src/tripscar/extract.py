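"""Internal-index demultiplexing and reporter-barcode extraction.

A read carries (5'->3'): an optional internal sample index, the constant
``adapter_5p``, the 16 bp (tolerated 15-17 bp) reporter barcode, the constant
``adapter_3p``, and the scar region. The barcode is recovered with a
three-step strategy: (1) match both adapter arms around the barcode
("full"), (2) match only the 5' arm, (3) match only the 3' arm. Constant
patterns read through into the backbone are trimmed from the remainder's
3' end. Failures are recorded, never raised: one bad read cannot kill a run.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from ._seq import count_mismatches, find_approx, hamming, revcomp
from .config import ConfigError, PipelineParams, ReporterSpec

log = logging.getLogger(__name__)

STEPS = ("full", "five_prime", "three_prime")

#: adapter arms shorter than this tolerate no mismatches at all — in a 5 bp
#: arm even one substitution would cause spurious matches
MIN_TOLERANT_ARM_LEN = 10

#: minimum 3'-end overlap with a read-through constant pattern to trim it
MIN_READTHROUGH_OVERLAP = 6


@dataclass
class ExtractionResult:
    read_id: str
    barcode: Optional[str]
    step: str  # "full" | "five_prime" | "three_prime" | "failed"
    remainder: str
    sample: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.step != "failed"


@dataclass
class ExtractionStats:
    """Per-sample extraction counters; step counters + failed sum to total."""

    total: int = 0
    per_step: dict = field(default_factory=lambda: {s: 0 for s in STEPS})
    failed: int = 0
    readthrough_trimmed: int = 0
    index_unassigned: int = 0

    def record(self, result: ExtractionResult, trimmed: bool = False) -> None:
        self.total += 1
        if result.step == "failed":
            self.failed += 1
        else:
            self.per_step[result.step] += 1
        if trimmed:
            self.readthrough_trimmed += 1

    def check(self) -> None:
        assert self.total == sum(self.per_step.values()) + self.failed

    def as_dict(self) -> dict:
        d = {"total": self.total, **self.per_step, "failed": self.failed,
             "readthrough_trimmed": self.readthrough_trimmed,
             "index_unassigned": self.index_unassigned}
        return d


def _arm_tolerance(arm: str, params: PipelineParams) -> int:
    if len(arm) < MIN_TOLERANT_ARM_LEN:
        return 0
    return params.adapter_max_mismatches


def validate_index_table(index_table: dict[str, str], max_mismatch: int = 1) -> int:
    """Check index lengths and pairwise separation; return the index length.

    Indices must be equal length and pairwise Hamming distance
    > 2*max_mismatch, otherwise a read could match two samples at once.
    """
    lens = {len(i) for i in index_table}
    if len(lens) != 1:
        raise ConfigError("internal indices must all have equal length")
    indices = list(index_table)
    for i, a in enumerate(indices):
        for b in indices[i + 1 :]:
            if hamming(a, b) <= 2 * max_mismatch:
                raise ConfigError(
                    f"indices {a!r} and {b!r} are within 2*max_mismatch "
                    f"({2 * max_mismatch}) of each other"
                )
    return lens.pop()


def _assign_index(
    read: str, index_table: dict[str, str], k: int, max_mismatch: int
) -> tuple[Optional[str], str]:
    prefix = read[:k]
    if len(prefix) < k:
        return None, read
    hit = index_table.get(prefix)
    if hit is not None:  # exact fast path
        return hit, read[k:]
    matches = [
        s for idx, s in index_table.items()
        if count_mismatches(prefix, idx, max_mismatch) <= max_mismatch
    ]
    if len(matches) == 1:
        return matches[0], read[k:]
    return None, read


def demultiplex_index(
    read: str, index_table: dict[str, str], max_mismatch: int = 1
) -> tuple[Optional[str], str]:
    """Assign a sample from the read's 5' internal index and strip it.

    The sample is assigned iff exactly one index matches within
    ``max_mismatch`` Hamming distance at the very start of the read.
    """
    k = validate_index_table(index_table, max_mismatch)
    return _assign_index(read, index_table, k, max_mismatch)


def trim_readthrough(remainder: str, spec: ReporterSpec) -> str:
    """Remove read-through into the backbone from the remainder's 3' end.

    The reverse complements of the constant patterns (the 5' barcode adapter
    and the iPCR read-2 constant) are searched in the remainder, tolerating
    one substitution; the remainder is truncated before the earliest
    occurrence. A pattern truncated by the end of the read is trimmed when at
    least MIN_READTHROUGH_OVERLAP bases overlap.
    """
    patterns = [revcomp(spec.adapter_5p)]
    if spec.ipcr_read2_constant:
        patterns.append(revcomp(spec.ipcr_read2_constant))
    cut = len(remainder)
    for pat in patterns:
        pos = find_approx(remainder, pat, 1)
        if 0 <= pos < cut:
            cut = pos
        # partial pattern running off the 3' end
        m = len(pat)
        for start in range(max(0, len(remainder) - m + 1), len(remainder) - MIN_READTHROUGH_OVERLAP + 1):
            if start >= cut:
                break
            overlap = len(remainder) - start
            if count_mismatches(remainder[start:], pat[:overlap], 1) <= 1:
                cut = start
                break
    return remainder[:cut]


def extract_barcode(
    read: str, spec: ReporterSpec, params: PipelineParams, read_id: str = ""
) -> ExtractionResult:
    """Extract the reporter barcode from one (index-stripped) read.

    Step "full" requires both arms with 16 bp between them (15/17 bp are
    recovered when both arms match at those distances); "five_prime" and
    "three_prime" fall back on a single arm and assume the expected 16 bp.
    When an arm matches at several positions, the leftmost is used — the
    cassette sits at a fixed 5' position.
    """
    arm5, arm3 = spec.adapter_5p, spec.adapter_3p
    mm5, mm3 = _arm_tolerance(arm5, params), _arm_tolerance(arm3, params)
    lo, hi = spec.barcode_len_range
    exp = spec.barcode_len_expected

    def result(barcode, step, remainder):
        return ExtractionResult(read_id, barcode, step, remainder)

    if len(read) < len(arm5) + lo + len(arm3):
        return result(None, "failed", "")

    p5 = find_approx(read, arm5, mm5)
    if p5 >= 0:
        bc_start = p5 + len(arm5)
        # prefer the expected length, then shorter/longer tolerated lengths
        for blen in sorted(range(lo, hi + 1), key=lambda n: (abs(n - exp), n)):
            a3 = read[bc_start + blen : bc_start + blen + len(arm3)]
            if len(a3) == len(arm3) and count_mismatches(a3, arm3, mm3) <= mm3:
                barcode = read[bc_start : bc_start + blen]
                remainder = read[bc_start + blen + len(arm3) :]
                return result(barcode, "full", remainder)
        barcode = read[bc_start : bc_start + exp]
        if len(barcode) < lo:
            return result(None, "failed", "")
        remainder = read[bc_start + exp + len(arm3) :]
        return result(barcode, "five_prime", remainder)

    p3 = find_approx(read, arm3, mm3)
    if p3 >= exp:
        barcode = read[p3 - exp : p3]
        remainder = read[p3 + len(arm3) :]
        return result(barcode, "three_prime", remainder)

    return result(None, "failed", "")


def extract_ipcr_pair(
    read1: str,
    read2: str,
    spec: ReporterSpec,
    params: PipelineParams,
    read_id: str = "",
) -> tuple[ExtractionResult, Optional[str]]:
    """Barcode from iPCR read 1; genomic portion from read 2.

    Read 2 is accepted only when it carries the transposon-edge constant
    (``ipcr_read2_constant``); its genomic portion is everything beyond it.
    A pair failing either check is reported failed (never raised).
    """
    res1 = extract_barcode(read1, spec, params, read_id=read_id)
    pos = find_approx(read2, spec.ipcr_read2_constant, 1)
    genomic: Optional[str] = None
    if pos >= 0:
        genomic = read2[pos + len(spec.ipcr_read2_constant) :]
    if not res1.ok or genomic is None:
        return ExtractionResult(read_id, None, "failed", "", res1.sample), None
    return res1, genomic


def read_fastq(path: str) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) from a (possibly gzipped) FASTQ file."""
    import pysam

    with pysam.FastxFile(path) as fh:
        for entry in fh:
            yield entry.name, entry.sequence


def write_fastq(path: str, reads: Iterable[tuple[str, str]]) -> int:
    """Write (read_id, sequence) pairs as FASTQ with constant Q40; returns n."""
    opener = gzip.open if str(path).endswith(".gz") else open
    n = 0
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


def extract_reads(
    reads: Iterable[tuple[str, str]],
    spec: ReporterSpec,
    params: PipelineParams,
    index_table: Optional[dict[str, str]] = None,
) -> tuple[list[ExtractionResult], ExtractionStats]:
    """Run demultiplexing (optional), extraction and read-through trimming.

    ``reads`` is any iterable of (read_id, sequence); use :func:`read_fastq`
    for files. Stats counters are conserved: total = per-step + failed.
    """
    stats = ExtractionStats()
    if index_table is not None:
        k = validate_index_table(index_table, params.adapter_max_mismatches)
    results: list[ExtractionResult] = []
    for rid, seq in reads:
        sample = None
        if index_table is not None:
            sample, seq = _assign_index(seq, index_table, k, params.adapter_max_mismatches)
            if sample is None:
                stats.index_unassigned += 1
        res = extract_barcode(seq, spec, params, read_id=rid)
        res.sample = sample
        trimmed = False
        if res.ok and res.remainder:
            new = trim_readthrough(res.remainder, spec)
            trimmed = len(new) < len(res.remainder)
            res.remainder = new
        stats.record(res, trimmed=trimmed)
        results.append(res)
    stats.check()
    return results, stats
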