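"""Tests for trimming, k-mer graph construction, unitigs and blunt ends."""


import pytest

from plastid_linker.dbg_assembly import (KmerGraph, auto_min_count,
                                         blunt_end_fraction, build_graph,
                                         build_unitigs, trim_read, trim_reads)
from plastid_linker.reads import BarcodedReadPair
from plastid_linker.seq import canonical_kmer, revcomp

BASES = "ACGT"


def q(chars: str) -> str:
    """Quality string from per-base Phred scores given as characters."""
    return chars


def phred(*scores: int) -> str:
    return "".join(chr(s + 33) for s in scores)


class TestTrimReads:
    def test_high_quality_read_unchanged(self):
        seq = "ACGT" * 10
        assert trim_read(seq, phred(*[37] * 40), q=15) == seq

    def test_low_quality_tail_removed(self):
        # argmax of the suffix sum of (q - Q_i): 30 bases of Q30 contribute
        # -15 each, 10 bases of Q2 contribute +13 each; the maximum (130) is
        # at the boundary, so exactly the 10 Q2 bases go
        seq = "A" * 40
        qual = phred(*([30] * 30 + [2] * 10))
        assert trim_read(seq, qual, q=15) == "A" * 30

    def test_entirely_bad_read_dropped_and_counted(self):
        pair = BarcodedReadPair("p", "A" * 30, phred(*[2] * 30),
                                "C" * 30, phred(*[37] * 30), "B" * 14)
        result = trim_reads([pair], q=15, min_len=20)
        assert result.sequences == ["C" * 30]
        assert result.dropped == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            trim_read("ACGT", "II", q=15)


class TestBuildGraph:
    def test_small_read_canonical_dedup(self):
        # enumerate the 5 windows of ACGTACGT at k=4 and canonicalize by
        # hand: ACGT(palindrome), CGTA->CGTA? no: revcomp(CGTA)=TACG,
        # canonical min(CGTA,TACG)=CGTA; GTAC palindrome; TACG->CGTA;
        # ACGT again
        g = build_graph(["ACGTACGT"], k=4, min_count=1)
        expected = {}
        for i in range(5):
            km = canonical_kmer("ACGTACGT"[i:i + 4])
            expected[km] = expected.get(km, 0) + 1
        assert len(expected) == 3  # ACGT x2, CGTA x2, GTAC x1
        assert g.counts == expected

    def test_min_count_filters_singletons(self):
        g = build_graph(["ACGGCATCAA"], k=5, min_count=2)
        assert g.counts == {}

    def test_reverse_complement_doubling(self, make_dna):
        reads = [make_dna(60) for _ in range(20)]
        g1 = build_graph(reads, k=21, min_count=1)
        g2 = build_graph(reads + [revcomp(r) for r in reads], k=21, min_count=1)
        assert set(g1.counts) == set(g2.counts)
        assert all(g2.counts[k] == 2 * g1.counts[k] for k in g1.counts)

    def test_k_larger_than_reads_rejected(self):
        with pytest.raises(ValueError):
            build_graph(["ACGT"], k=10, min_count=1)

    def test_ambiguous_bases_skipped(self):
        g = build_graph(["ACGTNACGT"], k=4, min_count=1)
        assert all("N" not in km for km in g.counts)

    def test_auto_min_count_tracks_coverage(self):
        counts = {f"k{i}": 49 for i in range(100)}
        counts.update({f"e{i}": 1 for i in range(30)})
        assert auto_min_count(counts) == 7  # sqrt of weighted median 49


def brute_force_unitigs(g: KmerGraph) -> set[str]:
    """Independent unitig enumeration from first principles.

    Builds the full oriented adjacency, finds all maximal simple paths
    whose internal vertices have in/out degree exactly one, and returns
    the canonical sequences.
    """
    oriented = set()
    for km in g.counts:
        oriented.add(km)
        oriented.add(revcomp(km))
    succ = {x: [x[1:] + b for b in BASES if x[1:] + b in oriented]
            for x in oriented}
    pred = {x: [b + x[:-1] for b in BASES if b + x[:-1] in oriented]
            for x in oriented}

    def is_start(x):
        return len(pred[x]) != 1 or len(succ[pred[x][0]]) != 1

    out = set()
    seen_canon = set()
    for x in oriented:
        if not is_start(x):
            continue
        path = [x]
        seen = {canonical_kmer(x)}
        while True:
            s = succ[path[-1]]
            if len(s) != 1 or len(pred[s[0]]) != 1:
                break
            if canonical_kmer(s[0]) in seen:
                break
            path.append(s[0])
            seen.add(canonical_kmer(s[0]))
        seq = path[0] + "".join(p[-1] for p in path[1:])
        out.add(min(seq, revcomp(seq)))
        seen_canon.update(canonical_kmer(p) for p in path)
    # pure cycles
    remaining = {km for km in g.counts if km not in seen_canon}
    while remaining:
        x = min(remaining)
        path = [x]
        seen = {canonical_kmer(x)}
        while True:
            s = succ[path[-1]]
            if len(s) != 1:
                break
            if canonical_kmer(s[0]) in seen:
                break
            path.append(s[0])
            seen.add(canonical_kmer(s[0]))
        min_i = min(range(len(path)), key=lambda i: canonical_kmer(path[i]))
        path = path[min_i:] + path[:min_i]
        seq = path[0] + "".join(p[-1] for p in path[1:])
        out.add(min(seq, revcomp(seq)))
        remaining -= {canonical_kmer(p) for p in path}
    return out


class TestBuildUnitigs:
    def test_unique_linear_sequence_single_contig(self, make_dna):
        seq = make_dna(2000)
        g = build_graph([seq], k=31, min_count=1)
        contigs = build_unitigs(g, min_len=100)
        assert len(contigs) == 1
        assert contigs[0].sequence in (seq, revcomp(seq))

    def test_bubble_not_spanned(self, make_dna):
        x, y = make_dna(100), make_dna(100)
        a, b = make_dna(40), make_dna(40)
        reads = [x + a + y, x + b + y]
        g = build_graph(reads, k=15, min_count=1)
        contigs = build_unitigs(g, min_len=1)
        assert len(contigs) >= 3
        for c in contigs:
            assert not (x + a + y == c.sequence or x + b + y == c.sequence
                        or revcomp(x + a + y) == c.sequence
                        or revcomp(x + b + y) == c.sequence)

    def test_min_len_filters_everything(self, make_dna):
        g = build_graph([make_dna(200)], k=31, min_count=1)
        assert build_unitigs(g, min_len=10_000) == []

    def test_circular_component_single_contig(self, make_dna):
        circle = make_dna(500)
        doubled = circle + circle[:30]
        g = build_graph([doubled], k=31, min_count=1)
        contigs = build_unitigs(g, min_len=100)
        assert len(contigs) == 1
        assert len(contigs[0].sequence) == 500 + 30  # opened circle spells
        # every k-mer once: length = n + k - 1
        assert len(set(g.counts)) == 500

    def test_contig_kmers_subset_of_graph(self, make_dna):
        reads = [make_dna(150) for _ in range(30)]
        g = build_graph(reads, k=21, min_count=1)
        for c in build_unitigs(g, min_len=21):
            for i in range(len(c.sequence) - 20):
                assert canonical_kmer(c.sequence[i:i + 21]) in g.counts

    def test_idempotence(self, make_dna):
        reads = [make_dna(300) for _ in range(10)]
        g = build_graph(reads, k=25, min_count=1)
        contigs = build_unitigs(g, min_len=25)
        g2 = build_graph([c.sequence for c in contigs], k=25, min_count=1)
        contigs2 = build_unitigs(g2, min_len=25)
        assert sorted(c.sequence for c in contigs) == \
               sorted(c.sequence for c in contigs2)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_on_small_graphs(self, trial):
        import numpy as np
        rng = np.random.default_rng(100 + trial)
        base = "".join(np.array(list(BASES))[rng.integers(0, 4, size=300)])
        # introduce branching by adding mutated copies
        reads = [base[i:i + 60] for i in range(0, 240, 20)]
        mutated = list(base)
        for pos in rng.integers(10, 290, size=3):
            mutated[pos] = BASES[(BASES.index(mutated[pos]) + 1) % 4]
        mutated = "".join(mutated)
        reads += [mutated[i:i + 60] for i in range(0, 240, 20)]
        g = build_graph(reads, k=15, min_count=1)
        assert len(g.counts) <= 600
        ours = {c.sequence for c in build_unitigs(g, min_len=1)}
        assert ours == brute_force_unitigs(g)


class TestBluntEndFraction:
    def test_single_kmer_blunt_both_ways(self):
        g = KmerGraph(5, {canonical_kmer("ACGTC"): 1})
        assert blunt_end_fraction(g) == 1.0

    def test_circular_genome_no_blunt_ends(self, make_dna):
        circle = make_dna(400)
        g = build_graph([circle + circle[:20]], k=21, min_count=1)
        assert blunt_end_fraction(g) == 0.0

    def test_linear_sequence_two_ends(self, make_dna):
        seq = make_dna(200)
        g = build_graph([seq], k=21, min_count=1)
        L = len(g.counts)
        # brute-force: count vertices lacking a neighbour in either direction
        brute = 0
        for km in g.counts:
            succs = [km[1:] + b for b in BASES
                     if canonical_kmer(km[1:] + b) in g.counts]
            preds = [b + km[:-1] for b in BASES
                     if canonical_kmer(b + km[:-1]) in g.counts]
            if not succs or not preds:
                brute += 1
        assert brute == 2
        assert blunt_end_fraction(g) == pytest.approx(2 / L)

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError):
            blunt_end_fraction(KmerGraph(5, {}))
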