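"""Finished-genome evaluation: composition, ambiguity, coverage, inverted repeat.

These are the reporting operations applied to a finished plastid genome:
nucleotide composition and GC content over unambiguous bases, ambiguous-base
and gap-run accounting, fraction of a reference covered by placed reads, and
detection of the two-copy inverted repeat (two intervals whose sequences are
reverse complements up to a handful of substitutions — the short IR that is
a hallmark of conifer plastids).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from plastid_linker.seq import canonical_kmer, revcomp

_IUPAC_AMBIGUOUS = set("NRYSWKMBDHV")


@dataclass
class CompositionReport:
    percent_a: float
    percent_c: float
    percent_g: float
    percent_t: float
    gc_percent: float
    length: int
    unambiguous: int


def composition(genome: str) -> CompositionReport:
    """Base percentages over A/C/G/T only; ambiguous bases are excluded
    from the denominator."""
    if not genome:
        raise ValueError("empty sequence")
    genome = genome.upper()
    a, c, g, t = (genome.count(b) for b in "ACGT")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionReport(
        percent_a=100 * a / denom,
        percent_c=100 * c / denom,
        percent_g=100 * g / denom,
        percent_t=100 * t / denom,
        gc_percent=100 * (g + c) / denom,
        length=len(genome),
        unambiguous=denom,
    )


@dataclass
class AmbiguityReport:
    length: int
    resolved: int
    ambiguous: int
    n_runs: int
    run_mean: float
    run_sd: float          # sample sd (n-1); 0 when fewer than 2 runs
    run_sd_population: float


def ambiguity_stats(genome: str) -> AmbiguityReport:
    """Count IUPAC-ambiguous bases and maximal 'N' runs."""
    genome = genome.upper()
    ambiguous = sum(1 for b in genome if b in _IUPAC_AMBIGUOUS)
    runs = []
    i, n = 0, len(genome)
    while i < n:
        if genome[i] == "N":
            j = i
            while j < n and genome[j] == "N":
                j += 1
            runs.append(j - i)
            i = j
        else:
            i += 1
    if runs:
        mean = sum(runs) / len(runs)
        var_pop = sum((r - mean) ** 2 for r in runs) / len(runs)
        sd_pop = math.sqrt(var_pop)
        sd = (math.sqrt(sum((r - mean) ** 2 for r in runs) / (len(runs) - 1))
              if len(runs) > 1 else 0.0)
    else:
        mean = sd = sd_pop = 0.0
    return AmbiguityReport(len(genome), len(genome) - ambiguous, ambiguous,
                           len(runs), mean, sd, sd_pop)


@dataclass
class CoverageReport:
    depth: np.ndarray
    fraction_covered: float
    placed_reads: int
    total_reads: int


def read_coverage(reference: str, reads: Sequence[str], seed_k: int = 19
                  ) -> CoverageReport:
    """Per-base depth of the reference under exact-seed ungapped placement.

    Each read is placed at the locus of its first (5'-most) seed k-mer with
    a unique exact match in the reference, on either strand; the read's
    span is extended ungapped from the seed and clipped to the reference.
    Reads with no unique seed are ignored.
    """
    index: dict[str, list[tuple[int, str]]] = defaultdict(list)
    n = len(reference)
    rc_ref = revcomp(reference)
    for i in range(n - seed_k + 1):
        fwd = reference[i:i + seed_k]
        bwd = rc_ref[n - i - seed_k:n - i]
        if fwd <= bwd:
            index[fwd].append((i, "+"))
        else:
            index[bwd].append((i, "-"))
    depth = np.zeros(n, dtype=np.int32)
    placed = 0
    for read in reads:
        if len(read) < seed_k:
            continue
        hit = None
        for off in range(len(read) - seed_k + 1):
            seed = read[off:off + seed_k]
            if "N" in seed:
                continue
            canon = canonical_kmer(seed)
            hits = index.get(canon)
            if hits is None:
                continue
            if len(hits) != 1:
                continue
            pos, strand = hits[0]
            fwd_match = (seed == canon) == (strand == "+")
            hit = (pos, off, fwd_match)
            break
        if hit is None:
            continue
        pos, off, fwd_match = hit
        if fwd_match:
            start = pos - off
        else:
            start = pos + seed_k - (len(read) - off)
        end = start + len(read)
        start, end = max(0, start), min(n, end)
        if end > start:
            depth[start:end] += 1
            placed += 1
    frac = float((depth >= 1).mean()) if n else 0.0
    return CoverageReport(depth, frac, placed, len(reads))


@dataclass
class IRReport:
    copy1: tuple[int, int] | None
    copy2: tuple[int, int] | None
    length: int
    substitutions: int

    @property
    def found(self) -> bool:
        return self.copy1 is not None


def detect_inverted_repeat(genome: str, min_anchor: int = 24) -> IRReport:
    """Find the longest two-copy inverted repeat by anchor merging.

    Maximal exact matches >= ``min_anchor`` between the genome and its
    reverse complement are collected; anchors on the same anti-diagonal
    (arising from one repeat pair interrupted by substitutions) are merged,
    counting the inter-anchor bases as substitutions.  The longest merged
    pair with disjoint copies is returned.
    """
    n = len(genome)
    if n < 2 * min_anchor:
        raise ValueError("sequence shorter than twice min_anchor")
    rc = revcomp(genome)
    # seed: exact matches of length min_anchor between genome and rc
    seeds: dict[str, list[int]] = defaultdict(list)
    for i in range(n - min_anchor + 1):
        seeds[genome[i:i + min_anchor]].append(i)
    # collect maximal extensions, dedup via set of (i, j, L)
    anchors: set[tuple[int, int, int]] = set()
    for j in range(n - min_anchor + 1):
        word = rc[j:j + min_anchor]
        for i in seeds.get(word, ()):
            # extend left
            bi, bj = i, j
            while bi > 0 and bj > 0 and genome[bi - 1] == rc[bj - 1]:
                bi -= 1
                bj -= 1
            L = min_anchor + (i - bi)
            # extend right
            while bi + L < n and bj + L < n and genome[bi + L] == rc[bj + L]:
                L += 1
            anchors.add((bi, bj, L))
    # translate rc coordinates back to genome coordinates:
    # rc[j:j+L] == revcomp(genome[n-j-L : n-j])
    pairs = []
    for i, j, L in anchors:
        c2 = (n - j - L, n - j)
        c1 = (i, i + L)
        if c1[0] >= c2[0]:
            continue  # keep one of each symmetric duplicate; require copy1 first
        if c1[1] > c2[0]:
            continue  # overlapping (palindromic self-hit)
        # anchors of one repeat pair share copy1_start + copy2_end = i + n - j,
        # so i - j indexes the anti-diagonal
        pairs.append((c1, c2, i - j))
    if not pairs:
        return IRReport(None, None, 0, 0)
    # merge anchors sharing an anti-diagonal
    by_diag: dict[int, list[tuple[tuple[int, int], tuple[int, int]]]] = defaultdict(list)
    for c1, c2, diag in pairs:
        by_diag[diag].append((c1, c2))
    best = None
    for diag, group in by_diag.items():
        group.sort()
        merged_c1 = [group[0][0][0], group[0][0][1]]
        merged_c2 = [group[0][1][0], group[0][1][1]]
        subs = 0
        ok = True
        prev_end = group[0][0][1]
        for c1, c2 in group[1:]:
            g = c1[0] - prev_end
            if g < 0:
                ok = False
                break
            subs += g
            prev_end = c1[1]
            merged_c1[1] = max(merged_c1[1], c1[1])
            merged_c2[0] = min(merged_c2[0], c2[0])
            merged_c2[1] = max(merged_c2[1], c2[1])
        if not ok:
            continue
        if merged_c1[1] > merged_c2[0]:
            continue
        length = merged_c1[1] - merged_c1[0]
        cand = (length, -subs, tuple(merged_c1), tuple(merged_c2), subs)
        if best is None or cand > best:
            best = cand
    if best is None:
        return IRReport(None, None, 0, 0)
    length, _, c1, c2, subs = best
    return IRReport(tuple(c1), tuple(c2), length, subs)


@dataclass
class ComparisonReport:
    exact_match: bool
    length_difference: int
    mismatches: int | None   # None when lengths differ
    orientation: str         # '+', '-' or 'n/a'


def compare_to_truth(assembly: str, truth: str, circular: bool = False
                     ) -> ComparisonReport:
    """Compare an assembly with its ground truth, rotation/strand aware.

    For circular sequences every rotation of either strand counts as an
    exact match; for equal-length non-matching sequences the best rotation's
    mismatch count is reported.
    """
    if not assembly or not truth:
        raise ValueError("empty sequence")
    ldiff = len(assembly) - len(truth)
    if not circular:
        mism = (sum(a != b for a, b in zip(assembly, truth))
                if ldiff == 0 else None)
        return ComparisonReport(assembly == truth, ldiff, mism, "+")
    if ldiff != 0:
        return ComparisonReport(False, ldiff, None, "n/a")
    doubled = assembly + assembly
    for strand, label in ((truth, "+"), (revcomp(truth), "-")):
        if strand in doubled:
            return ComparisonReport(True, 0, 0, label)
    # no exact rotation: report mismatches at the best anchored rotation
    best = None
    best_orient = "+"
    for strand, label in ((truth, "+"), (revcomp(truth), "-")):
        probe = strand[:min(31, len(strand))]
        start = doubled.find(probe)
        offsets = []
        while start != -1:
            offsets.append(start)
            start = doubled.find(probe, start + 1)
        if not offsets:
            offsets = [0]
        for off in offsets:
            rot = doubled[off:off + len(assembly)]
            mism = sum(a != b for a, b in zip(rot, strand))
            if best is None or mism < best:
                best, best_orient = mism, label
    return ComparisonReport(False, 0, best, best_orient)
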