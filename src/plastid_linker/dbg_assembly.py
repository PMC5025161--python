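"""Quality trimming, canonical k-mer de Bruijn graph, unitigs, blunt ends.

The graph is an implicit de Bruijn graph: a multiset of canonical k-mers.
Unitigs (maximal non-branching paths, reverse-complement aware) are the
contigs; no tip or bubble removal is performed — in this method the barcode
binning, not graph simplification, is what keeps the graph simple.  The
"blunt end" fraction (vertices lacking a neighbour in at least one
direction) is the graph-complexity metric used to compare assemblies of
different read subsets.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from plastid_linker.reads import BarcodedReadPair
from plastid_linker.seq import canonical_kmer, revcomp

BASES = "ACGT"


@dataclass
class KmerGraph:
    """Canonical k-mer multiset serving as an implicit de Bruijn graph."""

    k: int
    counts: dict[str, int]

    def __contains__(self, kmer: str) -> bool:
        return canonical_kmer(kmer) in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    def successors(self, kmer: str) -> list[str]:
        """Existing one-base forward extensions of an oriented k-mer."""
        stem = kmer[1:]
        return [stem + b for b in BASES if canonical_kmer(stem + b) in self.counts]

    def predecessors(self, kmer: str) -> list[str]:
        stem = kmer[:-1]
        return [b + stem for b in BASES if canonical_kmer(b + stem) in self.counts]


@dataclass
class Contig:
    id: str
    sequence: str
    mean_coverage: float

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TrimResult:
    sequences: list[str]
    dropped: int


def trim_read(seq: str, qual: str, q: int) -> str:
    """3' quality trim by the running-sum argmax (Mott) rule.

    Scanning from the 3' end, accumulate (q - Q_i); cut at the position that
    maximizes the suffix sum.  A read of uniformly high quality is returned
    unchanged; a read whose suffix dips below ``q`` loses that suffix.
    """
    if len(seq) != len(qual):
        raise ValueError("read/quality length mismatch")
    best, best_pos, s = 0, len(seq), 0
    for i in range(len(seq) - 1, -1, -1):
        s += q - (ord(qual[i]) - 33)
        if s > best:
            best, best_pos = s, i
    return seq[:best_pos]


def trim_reads(reads: Iterable[BarcodedReadPair], q: int = 15,
               min_len: int = 48) -> TrimResult:
    """Trim both mates of each pair; mates shorter than ``min_len`` after
    trimming are dropped and counted."""
    seqs, dropped = [], 0
    for pair in reads:
        for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
            t = trim_read(seq, qual, q)
            if len(t) >= min_len:
                seqs.append(t)
            else:
                dropped += 1
    return TrimResult(seqs, dropped)


def build_graph(reads: Iterable[str], k: int, min_count: int = 2) -> KmerGraph:
    """Count canonical k-mers of the reads; drop entries below ``min_count``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k % 2 == 0:
        warnings.warn("even k allows palindromic k-mers; canonical ties are "
                      "broken lexicographically", stacklevel=2)
    counts: Counter[str] = Counter()
    saw_read = False
    for seq in reads:
        saw_read = True
        rc = revcomp(seq)
        n = len(seq)
        if n < k:
            continue
        last_bad = -1
        for i, c in enumerate(seq):
            if c not in "ACGT":
                last_bad = i
            if i >= k - 1 and last_bad <= i - k:
                fwd = seq[i - k + 1 : i + 1]
                bwd = rc[n - i - 1 : n - i - 1 + k]
                counts[fwd if fwd <= bwd else bwd] += 1
    if saw_read and not counts:
        # distinguish "no k-mers because k exceeds every read" from empty input
        raise ValueError(f"k={k} exceeds every read length")
    if min_count > 1:
        counts = Counter({km: c for km, c in counts.items() if c >= min_count})
    return KmerGraph(k, dict(counts))


def auto_min_count(counts: dict[str, int]) -> int:
    """Coverage-adaptive count cutoff: sqrt of the median multiplicity.

    At high depth, sequencing errors recur and a fixed cutoff of 2 leaves
    bubble branches in the graph; the square root of the median k-mer
    multiplicity (the classic automatic coverage-cutoff heuristic) removes
    them while keeping true k-mers, whose counts concentrate near the
    median.  The median is occurrence-weighted (the multiplicity of a
    random k-mer occurrence), so the mass of distinct single-copy error
    k-mers does not drag it down.  Never below 2.
    """
    if not counts:
        return 2
    values = sorted(counts.values())
    total = sum(values)
    acc = 0
    median = values[-1]
    for v in values:
        acc += v
        if acc * 2 >= total:
            median = v
            break
    return max(2, round(median ** 0.5))



def build_unitigs(g: KmerGraph, min_len: int = 500) -> list[Contig]:
    """Maximal non-branching paths of the graph as contigs.

    Internal vertices have exactly one predecessor and one successor
    (reverse-complement aware).  Non-branching circular components emit one
    contig opened at their lexicographically minimal canonical k-mer.
    Output order is deterministic: sorted by canonical-orientation sequence.
    """
    if not g.counts:
        return []
    k = g.k
    visited: set[str] = set()
    unitig_seqs: set[str] = set()
    results: list[tuple[str, float]] = []

    def walk(start: str) -> tuple[str, list[str]]:
        """Extend right from an oriented start k-mer until a junction."""
        path = [start]
        seen = {canonical_kmer(start)}
        current = start
        while True:
            succs = g.successors(current)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if len(g.predecessors(nxt)) != 1:
                break
            cn = canonical_kmer(nxt)
            if cn in seen:
                break  # closed a loop
            path.append(nxt)
            seen.add(cn)
            current = nxt
        seq = path[0] + "".join(p[-1] for p in path[1:])
        return seq, path

    # linear unitigs: start from every junction-adjacent oriented k-mer
    for canon in g.counts:
        for kmer in {canon, revcomp(canon)}:
            preds = g.predecessors(kmer)
            is_start = (len(preds) != 1
                        or len(g.successors(preds[0])) != 1)
            if not is_start:
                continue
            seq, path = walk(kmer)
            canon_path = [canonical_kmer(p) for p in path]
            visited.update(canon_path)
            cseq = min(seq, revcomp(seq))
            if cseq not in unitig_seqs:
                unitig_seqs.add(cseq)
                cov = sum(g.counts[c] for c in canon_path) / len(canon_path)
                results.append((cseq, cov))

    # remaining vertices belong to fully non-branching circular components
    for canon in sorted(g.counts):
        if canon in visited:
            continue
        seq, path = walk(canon)
        canon_path = [canonical_kmer(p) for p in path]
        # open the circle at the lexicographically minimal canonical k-mer
        min_idx = min(range(len(canon_path)), key=lambda i: canon_path[i])
        path = path[min_idx:] + path[:min_idx]
        seq = path[0] + "".join(p[-1] for p in path[1:])
        visited.update(canon_path)
        cseq = min(seq, revcomp(seq))
        if cseq not in unitig_seqs:
            unitig_seqs.add(cseq)
            cov = sum(g.counts[c] for c in canon_path) / len(canon_path)
            results.append((cseq, cov))

    results.sort(key=lambda r: r[0])
    contigs = [Contig(f"contig{i}", seq, cov)
               for i, (seq, cov) in enumerate(results) if len(seq) >= min_len]
    return contigs


def blunt_end_fraction(g: KmerGraph) -> float:
    """Fraction of vertices with zero extensions in at least one direction.

    Neighbour lookup is reverse-complement aware; a single isolated k-mer is
    blunt in both directions and scores 1.0.
    """
    if not g.counts:
        raise ValueError("blunt-end fraction undefined for an empty graph")
    blunt = 0
    for canon in g.counts:
        if not g.successors(canon) or not g.predecessors(canon):
            blunt += 1
    return blunt / len(g.counts)
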