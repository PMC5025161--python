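# Methods

This note documents the models and algorithmic choices behind
`plastid-linker`: what the simulator emulates, how each pipeline stage
works, which parameters matter, and what the tests do and do not show
about real data.

## The linked-read simulator

The simulator produces the study conditions the pipeline is designed for:
a small circular organelle genome at high copy number inside a much larger
single-copy nuclear background, sequenced as barcoded linked reads.

**Genomes.** The organelle is an i.i.d. uniform A/C/G/T circle
(default 30,000 bp) carrying one planted two-copy inverted repeat (IR):
the second copy is the reverse complement of the first except at exactly
`ir_mismatches` positions (default 440 bp with 3 substitutions, the short
IR typical of conifer plastids). Substitution positions are evenly spaced
(quarter points of the repeat). This matters downstream: the longest
stretch identical between the two copies is then ~110 bp, so a k-mer of
111 or more spans at least one diagnostic difference and the two copies
can be phased by path search, while any smaller k genuinely cannot
distinguish them — the same length-scale reasoning that applies to real
repeat phasing. The repeat is made exactly maximal (the flanking bases are
chosen not to extend it), so detection has an unambiguous ground truth.
The nuclear background is a single linear i.i.d. sequence (default 1 Mb).
A related-species reference is derived from the organelle truth by i.i.d.
substitutions at `related_divergence` (default 1%, matching the ~99%
identity of congeneric plastid genomes); an optional small-indel mode
exists but is off by default.

**Library model.** A GEM draws a barcode uniformly *with replacement*
from a finite pool (default 5,000 14-mers), so barcodes are reused, and
Poisson(1.5) seed molecules. Each seed is organelle or nuclear; an
organelle seed brings a burst of `1 + Poisson(organelle_burst)` organelle
fragments (default burst mean 5), modelling the molar excess of small
plastid molecules in a droplet that captured plastid DNA. The seed-source
probability is adjusted so that the *marginal* fragment source fraction
still equals the copy-ratio-weighted mass fraction (6:1 organelle:nuclear
under the defaults, i.e. ~86% of fragments). The burst is what makes
high-multiplicity indices organelle-*enriched* rather than merely
organelle-*typical*: a model in which every fragment chooses its barcode
independently makes the organelle share of any multiplicity bin equal to
the overall share in expectation, and no threshold would enrich anything.
Fragment lengths are log-normal (median 20 kb, sigma 0.55), truncated to
[1 kb, 100 kb] and capped at the source length; organelle fragments may
wrap the circular origin. Reads per fragment are gamma-Poisson (negative
binomial, shape 0.4), giving the wide, overdispersed per-index count
distribution that real GemCode libraries show; per-index variance exceeds
the mean by an order of magnitude under the defaults. Pairs are 2x125 bp
with Normal(400, 50) insert sizes (resampled when they exceed the
fragment), i.i.d. substitution errors at 0.002/base, constant Q37
qualities decaying linearly to Q12 over the last 15 cycles (so quality
trimming at q=15 is exercised), and a 0.001 chance that the emitted index
carries one 'N'. Exactly `total_pairs` pairs are emitted; every pair has
one ground-truth row (source, fragment, barcode, coordinates, strand).

The fragment-length and reads-per-fragment distributions are modelling
choices, not measurements: the platform's true distributions are not
public at this granularity. They are exposed in `SimConfig`, chosen once
at values a linked-read practitioner would call unremarkable, and all
statistical claims in the tests (overdispersion, top-bin enrichment) are
asserted against the generator's own truth table rather than against
external data.

**What the simulator does not model:** PCR duplicates, chimeric
fragments, indel sequencing errors, barcode sequencing errors beyond the
'N' mechanism, GC bias, and any real genome's repeat landscape beyond the
single planted IR. Passing tests therefore demonstrate the *mechanics* of
binning, assembly and finishing under controlled conditions, not
performance on real libraries.

## Pipeline stages

**Binning.** The counting unit is the read pair. Indices containing 'N'
are excluded and tallied separately; conservation (counts + excluded =
total) is asserted. Bin thresholds are inclusive ("at least t pairs").
The pipeline selects thresholds from pair-fraction targets (defaults
0.40/0.15/0.05, the scaled-down analogues of bins that capture ~34%, ~2%
and ~1% of a real library): for a target f it takes the smallest
threshold whose bin holds at most a fraction f of all pairs. This mirrors
reading thresholds off the index-multiplicity distribution rather than
hard-coding counts that only make sense at one library size.

**Assembly.** Reads are 3'-trimmed by the running-sum argmax (Mott) rule
at q=15; mates shorter than k are dropped. Canonical k-mers (k=48;
lexicographic min of k-mer and reverse complement, even k accepted with a
warning) are counted, and counts below a cutoff are removed. The module
default cutoff is 2; the pipeline instead uses an occurrence-weighted
sqrt-of-median auto cutoff, because at the top bin's ~70x k-mer coverage
independent reads repeat the same error often enough that a cutoff of 2
leaves on the order of a hundred bubbles that fragment the unitigs. The
occurrence weighting makes the median reflect the multiplicity of a
random k-mer occurrence, so the large number of *distinct* singleton
error k-mers cannot drag it to 1. Unitigs are maximal non-branching
paths, reverse-complement aware; purely non-branching circular components
are opened at their lexicographically minimal canonical k-mer; output is
sorted by canonical sequence, hence deterministic. There is deliberately
no tip or bubble removal: in this method the read binning is what
simplifies the graph. The blunt-end fraction — vertices with zero
extensions in at least one direction — is the graph-complexity metric;
on the default simulation the top-bin graph scores ~1.4% against ~2.2%
for the all-reads graph, reproducing the qualitative contrast that
motivates binning.

**Scaffolding.** Pairs of 26-mers are extracted from the related
reference at every position, separated by a distance d swept over
250–2,000 (step 250), 2,000–9,000 (step 500) and 9,000–16,000 (step
1,000); each round's merged scaffolds feed the next. Only k-mers
occurring exactly once across all contigs are used (the IR is short
relative to the k-mer pair spans, so dropping repeated k-mers costs
little and avoids repeat-induced misjoins). A pair landing in two
different contigs votes for an oriented join with gap estimate
`d - (left k-mer to its contig's 3' end) - (right contig's 5' end to
right k-mer)`; votes aggregate per oriented join, the gap estimate is the
median vote. Layout is greedy: links below `min_support` (default 5) are
dropped, strongest first, each contig end accepts one partner, ties break
by smaller |gap| then contig id, and joins that would close a cycle are
rejected — so a circular genome comes out as a linear scaffold whose two
ends meet at the weakest junction. Gap estimates of one or more render as
that many 'N'; zero or negative estimates render as a single 'N'.

**Gap filling.** For each k in a descending sweep (125 down to 95 by 5,
then by 1 down to 35), a Bloom filter of read k-mers is built (canonical;
double hashing, two 64-bit halves of one blake2b digest; sized as
m = ceil(-n ln f / ln²2), h = round((m/n) ln 2) for target false-positive
rate f = 0.001). The start k-mer is the k-mer immediately left of the
gap, sliding outward up to F bases when absent; likewise the goal on the
right. Depth-first search extends one base at a time through filter
membership; every alternative explored at a fork counts toward the branch
budget B=3000; complete start-to-goal paths are collected up to P=20;
path length is capped at F plus the anchor span. One path closes the gap.
Several equal-length paths close it only via a strict consensus: pairwise
identity >= 95% *and* a strict majority in every column. A tied column
means the evidence cannot phase the locus — exactly what happens when
2^m chimeric paths thread an m-substitution inverted repeat — and the
sweep stops there (smaller k only collapses more context); the gap is
retried in a later round. Rounds go: most selective fill bin unenriched,
then per-gap enrichment with successive bins (default: the 15% bin, then
the 40% bin, then all reads). Enrichment anchors 500 bp gap flanks to the
related reference by unique exact 25-mer seeds (both orientations tried),
extracts the reference interval strictly between the anchored flank ends
padded by 24 bp, builds a k=25 Bloom filter from it and keeps read pairs
where either mate has >= 15% of its k-mers in the filter (default chosen
to tolerate ~1% divergence plus sequencing error at k=25; pairs are kept
intact so gap-spanning mates survive). Closed gaps splice their fill
(processed right-to-left so coordinates stay valid) and never reopen;
bases outside the spliced interval are byte-identical before and after.

**Circularization.** The scaffold's last and first 200 bp act as a
pseudo read pair; the same engine searches from the tail k-mer to the
head k-mer within 3,500 bp. The k may be a descending sweep (pipeline
default 125 down to 80 in steps of 5): a junction crossing the IR is
unphaseable below k=111 by the length-scale argument above, so large k is
tried first and 80 — the conventional end-joining k — is the floor. On a
unique connection (or strict consensus) the inter-end bases are appended;
the result is then rotated canonically (the unique occurrence of the
reference's first 31-mer goes to position 0, both strands tried;
otherwise the lexicographically minimal rotation over both strands).

**Evaluation.** Composition percentages use only unambiguous bases in
the denominator; GC is C+G. Ambiguity accounting counts all
IUPAC-ambiguous bases and maximal 'N' runs, reporting both sample (n−1,
primary) and population run-length standard deviations. Reference
coverage places each read at its first (5'-most) seed 19-mer with a
unique exact match on either strand, extends ungapped and clips — a
deliberate simplification of aligner-based coverage that is adequate for
presence/absence at <= 1% divergence, though reads lying entirely within
a perfect repeat have no unique seed and are ignored (the planted IR's
substitutions every ~110 bp leave every 125 bp read a unique seed, so
coverage of the default simulation is unaffected). IR detection collects
maximal exact matches >= 24 bp between the genome and its reverse
complement, merges anchors that share an anti-diagonal (copy1 start +
copy2 end constant) counting inter-anchor bases as substitutions, and
returns the longest merged pair with disjoint copies; indel-bearing IRs
are out of scope since only substitution mismatches are modelled.

## Determinism and seeds

Every stage is deterministic given its inputs; all randomness enters
through `SimConfig.seed`, fanned out to independent numpy generators per
stage (`[seed, stage-index]` seed sequences). Identical config and seed
reproduce byte-identical FASTQ, truth tables, reports and final FASTA.
Hashes (Bloom filter, k-mer indexing) are keyed blake2b, stable across
processes and platforms.

## Problem sizes

The default simulated study — 30 kb organelle, 200:1 copy ratio, 1 Mb
nuclear background, 200,000 pairs — was chosen as the smallest
configuration that preserves the method's working regime: the top ~1%
bin still covers the reference essentially completely (~16x read depth),
the assembly bin provides ~70x, and the nuclear background is deep enough
(~1.25x in the full read set) to complicate the all-reads graph but too
shallow to assemble, exactly the asymmetry the binning exploits. The full
pipeline on these defaults runs in well under a minute; the brute-force
oracle comparisons use graphs of at most ~10³ vertices where exhaustive
enumeration is exact.

## Known limitations

- The unitig assembler has no paired-end contiging, tip clipping or
  bubble popping; resolution beyond unitigs is delegated to
  reference-guided scaffolding, which presumes a colinear related genome.
- Scaffolding trusts reference colinearity; a rearranged reference would
  misjoin (the motivating failure of chimeric reference-guided
  assemblies).
- Gap-estimate accuracy degrades with reference indel divergence; the
  default simulation's reference has substitutions only.
- Coverage placement ignores reads without a unique exact seed, so deep
  perfect repeats (longer than a read) would appear uncovered.
- The Bloom filter stores presence only; the path engine cannot weight
  branches by multiplicity, which is why ambiguity is resolved by
  escalating read sets rather than by coverage votes.
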