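"""Fully synthetic DSB-TRIP experiments with ground truth.

The simulator emits every input the pipeline consumes — a reporter spec, a
mini-genome, barcoded integrations, indel-PCR reads, iPCR read pairs with
their (trivially known) alignments — plus truth tables, so each stage can be
tested offline without real sequencing data or an external aligner.

What it emulates: the reporter read structure (internal sample index,
constant barcode adapter arms, 16 bp barcode, cut site, seven downstream
6-mer spacers between offsets 83 and 124), an engineered 3 bp direct repeat
flanking the cut so the signature MMEJ product (-7 bp deletion, 3 bp
microhomology) exists by construction, ~2000 indel reads per reporter,
substitution-only sequencing error, barcode mutation, iPCR circular-ligation
chimeras (leading soft-clips), and clonal drift of barcode proportions over
time. Error model is substitution-only: indel sequencing errors would
confound truth bookkeeping and are not needed to exercise any stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import revcomp
from .config import PipelineParams, ReporterSpec
from .mapping import AlignedRead

BASES = np.array(list("ACGT"))

ADAPTER_5P = "GTCACAAGGGCCGGCCACAA"
ADAPTER_3P = "TGATC"

#: wild-type spacer offsets, spanning the 83-124 bp window downstream of the cut
SPACER_OFFSETS = (83, 90, 97, 104, 111, 118, 124)

# engineered microhomology geometry: a 3 bp direct repeat at [24,27) and
# [31,34) with the blunt cut inside the 4 bp between them; MMEJ collapse
# deletes 7 bp, left-aligned interval [24,31), microhomology 3
REPEAT_LEFT = 24
REPEAT_LEN = 3
REPEAT_GAP = 4
CUT_OFFSET = 29
AMPLICON_LEN = 131
RECOGNITION_HALF = 12


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic experiment.

    Defaults follow the protocol's guidance: 150 bp single-end reads, a
    median ~2000 indel reads per reporter, pools of ~100 integrations, and
    programmed MMEJ fractions spread across (0.05, 0.95).
    """

    seed: int = 0
    n_integrations: int = 100
    genome_size: int = 100_000
    read_len: int = 150
    depth_per_barcode: int = 2000
    ipcr_depth: int = 50
    substitution_error_rate: float = 0.0
    barcode_mutation_rate: float = 0.0
    chimera_rate: float = 0.0
    wt_fraction: float = 0.5
    mmej_fraction_range: tuple[float, float] = (0.05, 0.95)
    indel_spectrum: Optional[dict] = None  # outcome -> probability; overrides mmej draw
    index_len: int = 10
    n_samples: int = 1
    # drift
    n_clones: int = 20
    drift_days: tuple[int, ...] = (0, 4, 8, 12, 16, 20)
    growth_rate_sigma: float = 0.2


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_reporter(seed: int) -> ReporterSpec:
    """Build a random reporter spec that passes validation.

    The amplicon carries the engineered MMEJ repeat around the cut and seven
    unique 6-mer spacers at the wild-type offsets; construction retries until
    every structural invariant (spacer uniqueness, adapter absence from the
    scar region) holds, so the result is deterministic in the seed.
    """
    rng = np.random.default_rng(seed)
    for _ in range(200):
        amp = list(_random_seq(rng, AMPLICON_LEN))
        repeat = _random_seq(rng, REPEAT_LEN)
        amp[REPEAT_LEFT : REPEAT_LEFT + REPEAT_LEN] = repeat
        right = REPEAT_LEFT + REPEAT_LEN + REPEAT_GAP
        amp[right : right + REPEAT_LEN] = repeat
        spacers = []
        for off in SPACER_OFFSETS:
            s = _random_seq(rng, 6)
            amp[off : off + 6] = s
            spacers.append((s, off))
        wt = "".join(amp)
        constant2 = _random_seq(rng, 16)
        spec = ReporterSpec(
            wt_amplicon=wt,
            adapter_5p=ADAPTER_5P,
            adapter_3p=ADAPTER_3P,
            cut_offset=CUT_OFFSET,
            spacers=spacers,
            recognition_seqs={
                "wt": wt[CUT_OFFSET - RECOGNITION_HALF : CUT_OFFSET + RECOGNITION_HALF]
            },
            ipcr_read2_constant=constant2,
        )
        if ADAPTER_3P in wt or ADAPTER_5P in wt:
            continue
        if constant2 in wt:
            continue
        try:
            spec.validate()
        except Exception:
            continue
        # recognition window must be unique in the amplicon
        if wt.count(spec.recognition_seqs["wt"]) != 1:
            continue
        return spec
    raise RuntimeError("could not build a valid reporter spec")


def mmej_deletion_product(spec: ReporterSpec) -> str:
    """The engineered -7 MMEJ collapse product (one repeat copy retained)."""
    wt = spec.wt_amplicon
    return wt[:REPEAT_LEFT] + wt[REPEAT_LEFT + REPEAT_LEN + REPEAT_GAP :]


def _variant_remainder(spec: ReporterSpec, outcome, rng: np.random.Generator) -> tuple[str, int, int]:
    """Remainder sequence, net indel size and microhomology for an outcome.

    Outcomes: "wt"; a negative int d (deletion of |d| bp; -7 is the MMEJ
    repeat collapse, others delete at the cut); a positive int (insertion of
    random bases at the cut, drawn once per call).
    """
    wt = spec.wt_amplicon
    cut = spec.cut_offset
    if outcome == "wt":
        return wt, 0, 0
    size = int(outcome)
    if size == -(REPEAT_LEN + REPEAT_GAP):  # the engineered MMEJ product
        return mmej_deletion_product(spec), size, REPEAT_LEN
    if size < 0:
        d = -size
        # delete centred on the cut where possible
        start = max(0, cut - d // 2)
        return wt[:start] + wt[start + d :], size, 0
    ins = _random_seq(rng, size)
    return wt[:cut] + ins + wt[cut:], size, 0


def _mutate_barcode(bc: str, rng: np.random.Generator) -> str:
    """One random edit (substitution, insertion or deletion) in a barcode."""
    kind = rng.integers(3)
    pos = int(rng.integers(len(bc)))
    if kind == 0:  # substitution
        alt = [b for b in "ACGT" if b != bc[pos]]
        return bc[:pos] + alt[int(rng.integers(3))] + bc[pos + 1 :]
    if kind == 1:  # insertion
        return bc[:pos] + str(rng.choice(BASES)) + bc[pos:]
    return bc[:pos] + bc[pos + 1 :]  # deletion


def _inject_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n, replace=False):
        alt = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alt[int(rng.integers(3))]
    return "".join(out)


def make_index_table(n: int, length: int, rng: np.random.Generator) -> dict[str, str]:
    """Internal sample indices with pairwise Hamming distance >= 3."""
    indices: list[str] = []
    while len(indices) < n:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, prev)) > 2 for prev in indices):
            indices.append(cand)
    return {idx: f"s{i + 1}" for i, idx in enumerate(indices)}


def draw_integrations(
    spec: ReporterSpec, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Barcoded integrations with positions, strands and programmed balances.

    Barcodes are 16-mers kept pairwise Levenshtein distance >= 3 apart so
    genuine clusters are unambiguous; positions keep a 300 bp separation.
    """
    import edlib

    barcodes: list[str] = []
    while len(barcodes) < cfg.n_integrations:
        cand = _random_seq(rng, 16)
        if ADAPTER_3P in cand:
            continue
        if all(
            edlib.align(cand, prev, task="distance", k=2)["editDistance"] == -1
            for prev in barcodes
        ):
            barcodes.append(cand)
    margin = 300
    lo_m, hi_m = cfg.mmej_fraction_range
    positions: list[int] = []
    while len(positions) < cfg.n_integrations:
        p = int(rng.integers(margin, cfg.genome_size - margin))
        if all(abs(p - q) >= margin for q in positions):
            positions.append(p)
    strands = rng.choice(np.array(["+", "-"]), size=cfg.n_integrations)
    mmej = rng.uniform(lo_m, hi_m, size=cfg.n_integrations)
    return pd.DataFrame(
        {
            "barcode": barcodes,
            "chrom": "chr1",
            "pos": positions,
            "strand": strands,
            "mmej_fraction": mmej,
        }
    )


def _spectrum_for(cfg: SimulationConfig, mmej_fraction: float) -> dict:
    if cfg.indel_spectrum is not None:
        return cfg.indel_spectrum
    wt = cfg.wt_fraction
    return {"wt": wt, -7: (1 - wt) * mmej_fraction, 1: (1 - wt) * (1 - mmej_fraction)}


def simulate_indel_reads(
    spec: ReporterSpec,
    cfg: SimulationConfig,
    integrations: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame, dict[str, str]]:
    """Indel-PCR reads for every integration, with per-read truth.

    Returns (reads, truth, index_table): reads are (read_id, sequence) with
    the internal sample index prepended; truth has one row per read with the
    true barcode, outcome, indel size and microhomology. Reads shorter than
    the read length after a deletion read through into the backbone (the
    reverse complement of the 5' adapter), as on the real amplicon.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if integrations is None:
        integrations = draw_integrations(spec, cfg, rng)
    index_table = make_index_table(cfg.n_samples, cfg.index_len, rng)
    indices = list(index_table)
    readthrough = revcomp(spec.adapter_5p)

    reads: list[tuple[str, str]] = []
    truth_rows: list[dict] = []
    rid = 0
    for i, integ in enumerate(integrations.itertuples(index=False)):
        spectrum = _spectrum_for(cfg, integ.mmej_fraction)
        outcomes = list(spectrum)
        probs = np.array([spectrum[o] for o in outcomes], float)
        probs = probs / probs.sum()
        variant_cache = {
            o: _variant_remainder(spec, o, rng) for o in outcomes
        }
        draw = rng.choice(len(outcomes), size=cfg.depth_per_barcode, p=probs)
        sample_idx = indices[i % len(indices)]
        sample = index_table[sample_idx]
        for k in draw:
            outcome = outcomes[k]
            remainder, size, mh = variant_cache[outcome]
            barcode = integ.barcode
            mutated = False
            if cfg.barcode_mutation_rate > 0 and rng.random() < cfg.barcode_mutation_rate:
                barcode = _mutate_barcode(barcode, rng)
                mutated = True
            seq = (
                sample_idx + spec.adapter_5p + barcode + spec.adapter_3p + remainder
            )
            if len(seq) < cfg.read_len:
                pad = readthrough + _random_seq(rng, cfg.read_len)
                seq = seq + pad
            seq = seq[: cfg.read_len]
            seq = _inject_substitutions(seq, cfg.substitution_error_rate, rng)
            read_id = f"r{rid:07d}"
            rid += 1
            reads.append((read_id, seq))
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "barcode": integ.barcode,
                    "outcome": str(outcome),
                    "indel_size": size,
                    "microhomology_len": mh,
                    "barcode_mutated": mutated,
                }
            )
    return reads, pd.DataFrame(truth_rows), index_table


def naive_align(seq: str, genome: str, chrom: str = "chr1"):
    """Exact-match placement of seq in the mini-genome (both strands).

    Returns (chrom, pos, strand, ref_len) when the sequence occurs exactly
    once over both strands, else None. This is the simulator's stand-in for
    a genome aligner: on synthetic error-free fragments exact search is the
    correct alignment.
    """
    hits = []
    start = genome.find(seq)
    while start >= 0:
        hits.append((start, "+"))
        start = genome.find(seq, start + 1)
    rc = revcomp(seq)
    start = genome.find(rc)
    while start >= 0:
        hits.append((start, "-"))
        start = genome.find(rc, start + 1)
    if len(hits) != 1:
        return None
    pos, strand = hits[0]
    return (chrom, pos, strand, len(seq))


def simulate_ipcr(
    spec: ReporterSpec,
    cfg: SimulationConfig,
    integrations: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """iPCR read pairs plus their truth-consistent alignments.

    Read 1 carries the barcode cassette followed by genomic sequence running
    to the nearest upstream DpnII site (GATC); read 2 starts with the
    transposon-edge constant followed by the flank adjacent to the
    integration. A ``chimera_rate`` fraction of fragments splice a distant
    locus into the circle: their read-2 alignments sit at the distant locus
    with the true flank soft-clipped at the 5' end, exactly the artifact the
    soft-clip triage must repair.

    Returns a dict with keys: pairs (read_id, seq1, seq2), r1 / r2
    (AlignedRead lists), genome, integrations, truth (per-read).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    genome = _random_seq(rng, cfg.genome_size)
    if integrations is None:
        integrations = draw_integrations(spec, cfg, rng)
    const2 = spec.ipcr_read2_constant
    flank_len = cfg.read_len - len(const2)

    pairs = []
    r1_reads: list[AlignedRead] = []
    r2_reads: list[AlignedRead] = []
    truth_rows = []
    rid = 0
    for integ in integrations.itertuples(index=False):
        p, strand = int(integ.pos), str(integ.strand)
        for _ in range(cfg.ipcr_depth):
            read_id = f"i{rid:07d}"
            rid += 1
            # read 2: transposon edge into the adjacent genome
            if strand == "+":
                true_flank = genome[p : p + flank_len]
                aln_pos, aln_strand = p, "+"
            else:
                true_flank = revcomp(genome[p - flank_len + 1 : p + 1])
                aln_pos, aln_strand = p - flank_len + 1, "-"
            chimeric = cfg.chimera_rate > 0 and rng.random() < cfg.chimera_rate
            if chimeric:
                keep = int(rng.integers(5, 41))  # true flank retained before junction
                dpos = int(rng.integers(200, cfg.genome_size - 200 - flank_len))
                distal = genome[dpos : dpos + flank_len]
                body = (true_flank[:keep] + distal)[:flank_len]
                seq2 = const2 + body
                aligned_len = len(body) - keep
                # the aligner places the distal part and clips the true flank
                r2 = AlignedRead(
                    barcode=integ.barcode,
                    mate="r2",
                    chrom="chr1",
                    pos=dpos,
                    strand="+",
                    mapq=int(rng.integers(20, 42)),
                    leading_softclip_len=keep,
                    clipped_seq=true_flank[:keep],
                    ref_len=aligned_len,
                )
            else:
                seq2 = const2 + true_flank
                r2 = AlignedRead(
                    barcode=integ.barcode,
                    mate="r2",
                    chrom="chr1",
                    pos=aln_pos,
                    strand=aln_strand,
                    mapq=int(rng.integers(30, 42)),
                    ref_len=len(true_flank),
                )
            # read 1: barcode cassette, then genomic DNA on the other side of
            # the integration, ending at the nearest DpnII (GATC) junction
            cassette = spec.adapter_5p + integ.barcode + spec.adapter_3p
            room = cfg.read_len - len(cassette)
            if strand == "+":
                window = genome[p - room : p]
                dpn = window.rfind("GATC")
                if dpn >= 0:
                    window = window[dpn:]
                g1 = revcomp(window)
                pos1, strand1 = p - len(window), "-"
            else:
                window = genome[p + 1 : p + 1 + room]
                dpn = window.find("GATC")
                if dpn >= 0:
                    window = window[: dpn + 4]
                g1 = window
                pos1, strand1 = p + 1, "+"
            seq1 = cassette + g1
            r1 = AlignedRead(
                barcode=integ.barcode,
                mate="r1",
                chrom="chr1",
                pos=pos1,
                strand=strand1,
                mapq=int(rng.integers(30, 42)),
                ref_len=len(g1),
            )
            seq1 = _inject_substitutions(seq1, cfg.substitution_error_rate, rng)
            seq2 = _inject_substitutions(seq2, cfg.substitution_error_rate, rng)
            pairs.append((read_id, seq1, seq2))
            r1_reads.append(r1)
            r2_reads.append(r2)
            truth_rows.append(
                {
                    "read_id": read_id,
                    "barcode": integ.barcode,
                    "chrom": "chr1",
                    "pos": p,
                    "strand": strand,
                    "chimeric": chimeric,
                }
            )
    return {
        "pairs": pairs,
        "r1": r1_reads,
        "r2": r2_reads,
        "genome": genome,
        "integrations": integrations,
        "truth": pd.DataFrame(truth_rows),
    }


def integration_location_key(integrations: pd.DataFrame) -> pd.DataFrame:
    """Truth location key matching aggregate_locations' five_prime_pos.

    Read 2's 5'-most genomic base is the integration position itself on
    either strand, so the key is just (chrom, pos, strand).
    """
    out = integrations.copy()
    out["loc_pos"] = out["pos"]
    return out


def write_sam(path: str, reads: list[AlignedRead], genome_size: int, pairs=None) -> None:
    """Write AlignedReads as SAM with the barcode in a BC tag.

    The stored SEQ is synthesized from placeholders unless matching pair
    sequences are given; mapping only consumes coordinates, CIGAR and the
    clipped portion, which are always faithful.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": "chr1", "LN": int(genome_size)}],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"sim{i:07d}_BC={r.barcode}"
            a.reference_id = 0
            a.reference_start = r.pos
            a.mapping_quality = r.mapq
            a.is_reverse = r.strand == "-"
            clip = r.leading_softclip_len
            body = r.ref_len if r.ref_len else 1
            seq_clip = r.clipped_seq or ("N" * clip)
            seq_body = "A" * body
            if r.strand == "+":
                cig = ([(4, clip)] if clip else []) + [(0, body)]
                seq = seq_clip + seq_body if clip else seq_body
            else:
                cig = [(0, body)] + ([(4, clip)] if clip else [])
                seq = seq_body + seq_clip if clip else seq_body
            a.cigartuples = cig
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("BC", r.barcode)
            fh.write(a)


def simulate_drift(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Clonal drift of barcode proportions over culture time.

    Each clone grows exponentially with a log-normally distributed rate
    (sigma = growth_rate_sigma around a doubling-time-scale mean of 1/day);
    proportions are renormalized per sampling day. With any rate spread the
    fast clones take over, mirroring the observed pool takeover within two
    to three weeks.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    rates = rng.lognormal(mean=0.0, sigma=cfg.growth_rate_sigma, size=cfg.n_clones)
    n0 = np.ones(cfg.n_clones)
    rows = []
    for day in cfg.drift_days:
        sizes = n0 * np.exp(rates * day)
        props = sizes / sizes.sum()
        for i, pr in enumerate(props):
            rows.append({"day": day, "clone": f"bc{i:03d}", "proportion": pr})
    return pd.DataFrame(rows)


def gini(values) -> float:
    """Gini coefficient of a non-negative vector (0 = even, ->1 = skewed)."""
    v = np.sort(np.asarray(values, float))
    n = v.size
    if n == 0 or v.sum() == 0:
        return 0.0
    cum = np.cumsum(v)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def simulate_experiment(spec: ReporterSpec, cfg: SimulationConfig) -> dict:
    """One coherent experiment: shared integrations, indel + iPCR data.

    All randomness flows from cfg.seed; identical configs give identical
    outputs. Returns a dict with keys: spec, integrations, indel_reads,
    indel_truth, index_table, ipcr (see :func:`simulate_ipcr`).
    """
    rng = np.random.default_rng(cfg.seed)
    integrations = draw_integrations(spec, cfg, rng)
    indel_rng = np.random.default_rng(int(rng.integers(2**31)))
    ipcr_rng = np.random.default_rng(int(rng.integers(2**31)))
    reads, truth, index_table = simulate_indel_reads(
        spec, cfg, integrations=integrations, rng=indel_rng
    )
    ipcr = simulate_ipcr(spec, cfg, integrations=integrations, rng=ipcr_rng)
    return {
        "spec": spec,
        "integrations": integrations,
        "indel_reads": reads,
        "indel_truth": truth,
        "index_table": index_table,
        "ipcr": ipcr,
    }
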