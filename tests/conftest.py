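"""Shared fixtures and independent oracles.

The oracles here are deliberately written without reference to the package's
own implementations: a full dynamic-programming edit-distance matrix, an
all-pairs single-linkage clustering oracle, an independent re-statement of
the integration-filter predicates, and an exact rank-sum enumeration.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest

from tripscar import PipelineParams
from tripscar.simulate import make_reporter


@pytest.fixture(scope="session")
def spec():
    return make_reporter(7)


@pytest.fixture()
def params():
    return PipelineParams()


# ---------------------------------------------------------------- oracles


def dp_levenshtein(a: str, b: str) -> int:
    """Full O(nm) dynamic-programming edit-distance matrix."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[m]


def single_linkage_clusters(counts: dict[str, int], max_dist: int):
    """All-pairs connected components at distance <= max_dist.

    Returns member -> genuine mapping, the genuine barcode being the
    component's most abundant member (ties lexicographic).
    """
    barcodes = sorted(counts)
    parent = {b: b for b in barcodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(barcodes, 2):
        if dp_levenshtein(a, b) <= max_dist:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for b in barcodes:
        comps.setdefault(find(b), []).append(b)
    mapping = {}
    for members in comps.values():
        genuine = min(members, key=lambda m: (-counts[m], m))
        for m in members:
            mapping[m] = genuine
    return mapping


def location_filter_oracle(row, params: PipelineParams) -> bool:
    """Independent restatement of the four trustworthy-location predicates."""
    if row["reads1"] < params.min_ipcr_reads:
        return False
    if row["mapq_sum1"] / row["reads1"] <= params.min_avg_mapq:
        return False
    if row["reads1"] / row["total_reads"] < params.min_primary_frac:
        return False
    if row["reads2"] / row["total_reads"] > params.max_secondary_frac:
        return False
    return True


def exact_ranksum_p_less(x, y) -> float:
    """Exact one-sided P(rank sum of x as small or smaller | no difference).

    Enumerates every assignment of the pooled values' ranks to the x group;
    valid for small tie-free samples. Matches the Mann-Whitney "less"
    alternative (x stochastically smaller than y).
    """
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free values"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n = len(x)
    count = sum(
        1 for combo in itertools.combinations(range(1, len(pooled) + 1), n)
        if sum(combo) <= obs
    )
    return count / comb(len(pooled), n)


def random_barcode_pool(rng: np.random.Generator, n_true: int, min_sep: int = 5):
    """True barcodes pairwise distance >= min_sep (so clusters are unambiguous)."""
    bases = "ACGT"
    out: list[str] = []
    while len(out) < n_true:
        cand = "".join(rng.choice(list(bases), size=16))
        if all(dp_levenshtein(cand, prev) >= min_sep for prev in out):
            out.append(cand)
    return out


def mutate_once(bc: str, rng: np.random.Generator) -> str:
    kind = rng.integers(3)
    pos = int(rng.integers(len(bc)))
    if kind == 0:
        alt = [b for b in "ACGT" if b != bc[pos]]
        return bc[:pos] + alt[int(rng.integers(3))] + bc[pos + 1 :]
    if kind == 1:
        return bc[:pos] + str(rng.choice(list("ACGT"))) + bc[pos:]
    return bc[:pos] + bc[pos + 1 :]
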