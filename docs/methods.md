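# Methods

## Reporter model and coordinates

A reporter read (5′→3′) is: internal sample index · `adapter_5p`
(`GTCACAAGGGCCGGCCACAA`) · barcode (16 bp expected, 15–17 tolerated) ·
`adapter_3p` (`TGATC`) · scar region. All reporter coordinates
(`cut_offset`, spacer `expected_offset`) are 0-based positions in
**remainder coordinates**: position 0 is the first base after `adapter_3p`.
This origin is a package convention — the spacer window "83–124 bp" has no
defined origin in the assay's informal description — and the simulator and
the caller share it, so spacer-shift indel sizes are internally consistent.

With 150 bp reads, a 10 bp index and the 41 bp barcode cassette, ~99 bp of
remainder are visible on a wild-type read. Only the first spacer (offset
83, ending at 89) is then within view; that is sufficient to call indel
size 0 on intact reads, and deletions shift the later spacers into view.
Insertions larger than ~10 bp push every spacer (and the recognition
window) out of the read, which correctly yields `not_clear`.

## Barcode extraction

Three-step adapter matching: (1) both arms with 15/16/17 bp between them
("full", preferring 16); (2) 5′ arm only, barcode = next 16 bp; (3) 3′ arm
only, barcode = preceding 16 bp. Arm matching tolerates substitutions only
(≤ 1 per arm by default); arms shorter than 10 bp tolerate none, because a
single substitution in a 5 bp arm matches ~1 % of random positions. When an
arm matches at several positions the leftmost is used (the cassette sits at
a fixed 5′ position). The tolerant search uses pigeonhole chunk seeding so
error-free reads never pay for it. Read-through into the vector backbone is
trimmed by removing the reverse complements of the constant patterns from
the remainder's 3′ end, tolerating one substitution and accepting patterns
truncated by the end of the read (≥ 6 bp overlap). Failures are recorded in
per-sample statistics (counters are conserved: total = per-step + failed),
never raised.

Internal sample indices must be equal length with pairwise Hamming distance
> 2·max_mismatch; a read is assigned iff exactly one index matches within
tolerance at the read start.

## Barcode clustering

Greedy sphere clustering at Levenshtein radius 1 (i.e. distance < 2,
strict, as printed in the protocol): candidate centers by descending count,
ties broken lexicographically for determinism; every unassigned barcode
within the radius joins the current center, which becomes the cluster's
"genuine" barcode. Distances come from edlib's banded alignment.
Length-15/17 barcodes join 16-mer clusters naturally. The all-pairs
single-linkage construction is kept in the test suite as an independent
oracle; greedy spheres and single linkage agree unless a mutation chain
bridges two abundant centers, which the tests flag (and which cannot occur
in the simulator, whose true barcodes are kept ≥ 3 edits apart).
Cluster application supports both the filtering mode (drop non-genuine
rows) and the rescue mode (reassign and merge onto the genuine barcode).

## Integration mapping

Alignment itself is delegated — the module consumes SAM (barcode in a `BC`
tag or a `BC=` field of the read name) — because the assay's bespoke
content is the pre/post-processing, not the aligner. The transposon-edge
mate (read 2) locates the integration; circular-ligation chimeras appear as
leading 5′ soft-clips. Triage: no clip → keep; 1–16 bp → discard;
> 16 bp → realign the clipped sequence, which re-enters aggregation as an
ordinary read. Locations are keyed by (chromosome, strand, 5′-most genomic
base), with positions within ±2 bp collapsed to the modal position to
absorb end jitter. Per barcode the two best-supported locations are
reported with read counts and MAPQ sums (ties: count, MAPQ sum, chromosome,
position). Filters: reads1 ≥ 5, mean primary MAPQ > 10, primary fraction
≥ 0.95, secondary fraction ≤ 0.025; fractions are computed over **all** of
the barcode's reads (the looser reading of "of the reads"; the denominators
are parameterized). Filtering is monotone in primary support. Coordinates
are 0-based internally, 1-based only in exported TSV.

## Scar calling

Recognition matching is exact (0 mismatches): recognition sequences define
calls, and mismatched reads are already routed to size-based calls. The
longest matching named sequence wins. Indel size is the shift of the first
spacer found, using the occurrence nearest its expected offset (a 6-mer can
reappear by chance after mutation); one concordant spacer is required and
multi-spacer disagreements are logged at debug level. The call taxonomy is
total: named (incl. `wt`) → `del`/`ins`/`wt_point_mut` by size sign →
`not_clear`; the size is attached even when a recognition sequence is
found, so `wt` with size −1 is representable (mutation outside the targeted
window).

The alignment mode uses Biopython's `PairwiseAligner` (global; match +1,
mismatch −1, gap open −4, gap extend −1 — module defaults, since no
canonical values exist for this assay) with free right-end gaps, because
reads are right-truncated at the read length and overhang is not a
deletion. Alignments below 50 % identity over aligned columns fall back to
`not_clear`. Deletions are left-aligned before the microhomology is
measured; the microhomology length is the number of positions the deletion
can slide right, which equals the flanking direct-repeat length — the
convention under which the engineered −7 MMEJ product scores exactly 3.

## Pathway quantification

`not_clear` rows are removed (the removed fraction is logged, not
asserted — it is a property of each dataset). Cell estimates:
`reads_barcode / reads_total × 100,000 cells × 6 barcodes/cell`; estimates
sum to 600,000 by construction and barcodes under 50 estimated cells are
flagged for removal. Replicates are scaled to counts-per-million, averaged
per (barcode, call, size) with absent classes contributing zero, and
proportions computed on the averages, making results depth-invariant.

Signature classification: +1 → NHEJ; −7 → MMEJ (plus the known −14/MH3 and
−22/MH6 products), by size alone in count mode; when alignment details are
available a deletion class only counts as MMEJ in a barcode if the required
microhomology dominates its detailed reads. Wild-type reads are excluded
from every indel denominator; `mmej_fraction = MMEJ/(MMEJ+NHEJ)` is NaN
when no signature reads exist and is invariant to depth scaling.

Inhibitor-based NHEJ discovery: classes with pooled DMSO mean ratio ≥ 0.01
are tested with a one-sided Wilcoxon rank-sum test (inhibited < DMSO)
across per-barcode values — rank-sum across barcodes was chosen over a
paired signed-rank because barcodes are the replication unit; both the
ratio floor's pooling and the adjustment method (Benjamini–Hochberg, the
field default; unspecified in the protocol) are parameterized. Classes with
fewer than 3 observations per condition are reported untested, never
guessed. The scipy implementation is checked in the tests against a full
enumeration of rank-sum distributions for group sizes ≤ 8.

## Simulator

The simulator emulates: the reporter structure above, with an engineered
3 bp direct repeat at remainder positions [24,27) and [31,34) flanking the
cut (offset 29) so the −7/MH3 MMEJ product exists by construction; seven
unique 6-mers at offsets 83–124; per-reporter outcome spectra (default
wild-type fraction 0.5, MMEJ balance uniform on [0.05, 0.95], ~2000 reads
per reporter, matching the assay's depth guidance); substitution-only
sequencing error; single-edit barcode mutation; iPCR circles on a random
100 kb mini-genome with read 1 running to the nearest DpnII (GATC) site and
read 2 from the transposon edge; chimeric circles whose read-2 alignments
sit at a distant locus with the true flank soft-clipped (5–40 bp retained);
and clonal drift with log-normal growth-rate spread. All randomness flows
from one seed; outputs are byte-reproducible. Alignments are emitted
directly (they are known by construction); a naive exact-match aligner over
the mini-genome serves for soft-clip realignment.

What the simulator does **not** model — and hence what passing tests do not
establish about real data: indel sequencing errors, PCR jackpotting and
duplicates, quality-score variation, repetitive genomic sequence (mapping
ambiguity), large resections that destroy primer sites, and reporters
sharing a barcode by chance. The not_clear rate observed on real data
(reported around 17 % in the original analyses) therefore has no synthetic
counterpart; the simulator only produces not_clear reads when programmed
(e.g. via large insertions).

## Problem sizes and numerical choices

Validation runs use 100–200 reporters at 2000 reads (end-to-end identity
and balance recovery), 10,000 reads for spacer/alignment concordance, 500
barcodes against the clustering oracle, and 1000 null classes for the
false-NHEJ-label rate — sizes chosen to make sampling error small relative
to the tolerances they check. Degenerate inputs are defined errors (empty
count tables, empty barcode sets) or recorded failures (unextractable
reads, unmappable clips). Tie-breaks everywhere are deterministic
(lexicographic or by explicit sort keys) so repeated runs are identical.

## Known limitations

Homologous recombination leaves no indel and is invisible to this readout.
Only single-chromosome SAM output is exercised by the simulator, though the
mapping code is chromosome-agnostic. The greedy sphere clustering is not
starcode's message-passing mode; for the shallow satellite clouds of this
assay the two coincide (see oracle tests). `wt` calls conflate uncut and
perfectly repaired molecules; interpreting their abundance requires
experiment-level context.
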