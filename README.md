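# plastid-linker

Assembly of high-copy organelle (plastid) genomes from barcoded
linked-read sequencing data, from raw read pairs to a finished, circular,
gap-free sequence.

## The problem

Linked-read libraries partition long DNA fragments into droplets (GEMs);
every short read pair derived from one droplet carries the same 14 bp
index sequence. In a total-DNA library from a plant, the chloroplast
genome is present at hundreds of copies per nuclear genome, so droplets
that capture plastid DNA capture many plastid molecules at once and their
indices accumulate thousands of read pairs. Ranking indices by
multiplicity and keeping only the busiest ones therefore yields a small
read subset that is strongly enriched for plastid DNA and still covers
essentially the whole organelle genome — enough to assemble it without any
laboratory purification, and with a far simpler de Bruijn graph than the
full read set would give.

`plastid-linker` implements that whole strategy as a reusable library and
CLI:

1. **Binning** — count read pairs per N-free index; extract bins of all
   pairs whose index has at least *t* associated pairs.
2. **Assembly** — quality-trim (Mott 3' trimming, q=15), count canonical
   k-mers (default k=48), emit unitig contigs; quantify graph complexity
   as the *blunt-end fraction* (vertices with no neighbour in at least one
   direction).
3. **Scaffolding** — order and orient contigs with paired k-mers (k=26)
   extracted from a related reference genome at distances swept from
   250 bp to 16 kb, each round feeding the next.
4. **Gap filling** — close N-runs by bounded depth-first path search over
   a Bloom-filter de Bruijn graph of the reads, sweeping k from 125 down
   to 35 (limits B=3000 branch events, P=20 paths, F=5000 bp); when a gap
   resists, enrich reads per locus by anchoring the gap flanks to the
   related reference, extracting the spanning interval (+24 bp pad) and
   keeping only reads that share k-mers (k=25, FPR 0.001) with it.
5. **Circularization** — treat the scaffold's two ends as a pseudo read
   pair and connect them through the same path-search engine.
6. **Evaluation** — base composition and GC, ambiguity/gap accounting,
   reference coverage by exact-seed read placement (k=19), and detection
   of the two-copy inverted repeat (IR) by merging maximal exact matches
   between the genome and its reverse complement along anti-diagonals.

A linked-read simulator (`plastid_linker.synthetic_data`) generates a
circular organelle genome with a planted two-copy IR, a nuclear
background, and barcoded reads with overdispersed per-index multiplicities
and barcode reuse, plus per-pair ground truth — so the entire pipeline is
testable end to end with no downloads.

## Worked example

Run the default simulated study (30 kb organelle at 200:1 copy ratio,
1 Mb nuclear background, 200,000 read pairs, 1%-diverged related
reference):

```bash
plastid-linker run-all --seed 1 --outdir run1
```

which prints the final evaluation (from `run1/report.json`):

```json
{
  "length": 30000,
  "gc_percent": 49.6,
  "composition": {"A": 25.2, "C": 24.9, "G": 24.7, "T": 25.1},
  "ambiguous_bases": 0,
  "n_runs": 0,
  "circular": true,
  "inverted_repeat": {"found": true, "length": 440, "substitutions": 3,
                      "copy1": [6209, 6649], "copy2": [22658, 23098]},
  "truth_comparison": {"exact_match": true, "length_difference": 0,
                       "mismatches": 0, "orientation": "+"}
}
```

Reading this: the pipeline recovered a circular 30,000 bp genome with no
ambiguous bases; it is byte-identical to the simulated truth up to
rotation; and the planted 440 bp inverted repeat with exactly 3
substitutions between its copies was reconstructed faithfully. The
stage log in the report shows the intermediate numbers: the top ~5%
multiplicity bin (9,918 of 200,000 pairs) assembled into 2 contigs with a
blunt-end fraction of 0.0006, scaffolding against the related reference
produced one on-target scaffold with 1 gap, and the first gap-filling
round closed it.

Each stage is also available separately (`simulate`, `count-indices`,
`bin`, `assemble`, `scaffold`, `bloom-build`, `bloom-filter-reads`,
`fill`, `circularize`, `eval`) on FASTQ/FASTA files, so external data can
enter at any point; barcodes are read from `BX:Z:` header comments or,
with `--barcode-mode inline`, from the first 14 bases of read 1.

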