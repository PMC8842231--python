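# tripscar

Analysis of multiplexed, barcoded DNA double-strand-break (DSB) repair
reporters (DSB-TRIP / "Thousands of Reporters Integrated in Parallel"):
from raw sequencing reads to per-reporter repair-pathway balance.

## The problem

A short repair reporter is randomly integrated at hundreds to thousands of
genomic locations, each copy tagged by a random 16 bp barcode. A Cas9 cut is
induced inside every reporter; the cell's repair machinery leaves a
pathway-specific "scar" at the cut site — at the LBR2 target, a **+1 bp
insertion** is the signature of non-homologous end-joining (NHEJ) and a
**−7 bp deletion flanked by 3 bp microhomologies** is the signature of
microhomology-mediated end-joining (MMEJ). Sequencing the scar region
together with the barcode, and mapping each barcode's integration site by
inverse PCR (iPCR), yields the pathway balance of every reporter at its own
chromatin environment:

```
mmej_fraction = MMEJ / (MMEJ + NHEJ)
```

`tripscar` implements the full computational chain:

| stage | module | what it does |
|---|---|---|
| barcode extraction | `tripscar.extract` | internal-index demultiplexing; three-step adapter matching (full / 5′ / 3′) recovering 15–17 bp barcodes; read-through trimming |
| barcode clustering | `tripscar.cluster` | Levenshtein (< 2) greedy sphere clustering into genuine vs mutated barcodes; filter or rescue |
| integration mapping | `tripscar.mapping` | per-barcode top-2 locations from iPCR SAM alignments; chimera soft-clip triage (discard ≤ 16 bp, realign > 16 bp); filters: ≥ 5 reads, mean MAPQ > 10, ≥ 95 % primary, ≤ 2.5 % secondary |
| scar calling | `tripscar.scars` | exact recognition-sequence matching; indel size from the positional shift of seven downstream 6-mer spacers; call taxonomy (wt / named / del / ins / wt_point_mut / not_clear); optional pairwise-alignment mode with deletion intervals and microhomology lengths |
| pathway balance | `tripscar.pathway` | not_clear filtering; abundance-based cell estimates; replicate normalization; MMEJ/NHEJ classification (by signature size, by microhomology detail, or empirically from DNA-PK-inhibitor response with a one-sided Wilcoxon test and BH adjustment) |
| simulation | `tripscar.simulate` | complete synthetic experiments (reporter, mini-genome, indel + iPCR reads, alignments, clonal drift) with per-read ground truth |
| orchestration | `tripscar.cli` | `trip-scar` command: sample-sheet-driven stages with manifest + checksums |

## Worked example

```python
from tripscar import PipelineParams
from tripscar.simulate import SimulationConfig, make_reporter, simulate_experiment
from tripscar.pipeline import analyze_experiment

spec = make_reporter(7)
cfg = SimulationConfig(seed=0, n_integrations=12, depth_per_barcode=500,
                       substitution_error_rate=0.001, chimera_rate=0.05)
exp = simulate_experiment(spec, cfg)
out = analyze_experiment(exp)

print("extraction:", out["stats"].as_dict())
print("genuine barcodes:", out["cluster_table"]["genuine_barcode"].nunique())
print("integrations passing filters:",
      int((out["integration_calls"]["status"] == "pass").sum()))
res = out["joined"].merge(exp["integrations"][["barcode", "mmej_fraction"]],
                          on="barcode", suffixes=("", "_programmed"))
print(res[["barcode", "chrom", "pos", "strand", "mmej_count", "nhej_count",
           "mmej_fraction", "mmej_fraction_programmed"]].head().to_string(index=False))
```

prints

```
extraction: {'total': 6000, 'full': 5967, 'five_prime': 30, 'three_prime': 3, 'failed': 0, 'readthrough_trimmed': 0, 'index_unassigned': 0}
genuine barcodes: 12
integrations passing filters: 12
         barcode chrom   pos strand  mmej_count  nhej_count  mmej_fraction  mmej_fraction_programmed
AAAGTTGTTAATATTT  chr1 80006      +          71         179       0.284000                  0.359879
AACTCTCATTAAGCGA  chr1 38452      -         132         117       0.530120                  0.511483
ATAGACCCCAAAAGGG  chr1 51676      -          22         212       0.094017                  0.075529
CCCTACACTGCTGTAC  chr1 48010      -         193          58       0.768924                  0.807186
CGTCCTTTCGTGTGGC  chr1 96979      +         144          93       0.607595                  0.697298
```

All 6000 reads were extracted (99.5 % by matching both adapter arms; a
0.1 % substitution error rate occasionally knocks out one arm), the 12
genuine barcodes and all 12 integration sites were recovered exactly, and
each reporter's estimated `mmej_fraction` tracks the outcomes actually
drawn for it; the residual spread against the *programmed* balance is
multinomial sampling noise at ~250 informative reads per reporter.

The same analysis runs from the shell on files:

```sh
trip-scar run --outdir out --seed 0           # simulate + all stages
trip-scar extract --config cfg.yaml --samples samples.tsv --outdir out
trip-scar map --config cfg.yaml --sam ipcr.r2.sam --out out/pool.2.table
```

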