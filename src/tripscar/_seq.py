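"""Small nucleotide-string helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def count_mismatches(a: str, b: str, limit: int) -> int:
    """Mismatches between equal-length strings, bailing out once > limit."""
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def find_approx(seq: str, pattern: str, max_mismatch: int) -> int:
    """Leftmost occurrence of pattern in seq allowing substitutions only.

    Returns -1 when no window is within max_mismatch. Exact search is the
    fast path. The tolerant search uses pigeonhole seeding: a window with at
    most k substitutions must contain one of k+1 exact pattern chunks, so
    candidate positions come from C-speed substring search and only those
    windows are verified.
    """
    pos = seq.find(pattern)
    if pos >= 0 or max_mismatch <= 0:
        return pos
    m = len(pattern)
    if m > len(seq):
        return -1
    k = max_mismatch
    chunk = m // (k + 1)
    if chunk == 0:  # pattern too short to split; direct scan
        for start in range(len(seq) - m + 1):
            if count_mismatches(seq[start : start + m], pattern, k) <= k:
                return start
        return -1
    candidates: set[int] = set()
    for i in range(k + 1):
        off = i * chunk
        end = off + chunk if i < k else m
        piece = pattern[off:end]
        at = seq.find(piece)
        while at >= 0:
            start = at - off
            if 0 <= start <= len(seq) - m:
                candidates.add(start)
            at = seq.find(piece, at + 1)
    for start in sorted(candidates):
        if count_mismatches(seq[start : start + m], pattern, k) <= k:
            return start
    return -1


def find_all(seq: str, pattern: str) -> list[int]:
    """All (possibly overlapping) exact occurrence start positions."""
    out = []
    start = seq.find(pattern)
    while start >= 0:
        out.append(start)
        start = seq.find(pattern, start + 1)
    return out
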