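"""Tests for gap filling, enrichment, circularization and the path engine."""

import numpy as np
import pytest

from plastid_linker.finishing import (Gap, NotCircularizable,
                                      PathSearchLimits, UnanchoredError,
                                      _SetMembership, bounded_path_search,
                                      canonical_rotation, default_k_sweep,
                                      enrich_reads_for_gap, fill_all_gaps,
                                      fill_gap, find_gaps, join_ends,
                                      mask_region, splice_fill)
from plastid_linker.reads import BarcodedReadPair
from plastid_linker.seq import canonical_kmer, revcomp
from tests.conftest import random_dna

BASES = "ACGT"


def tile_reads(seq: str, read_len: int = 60, step: int = 7) -> list[str]:
    """Error-free reads tiling a sequence on both strands."""
    reads = [seq[i:i + read_len] for i in range(0, len(seq) - read_len + 1, step)]
    return reads + [revcomp(r) for r in reads]


def pairs_from_reads(reads: list[str]) -> list[BarcodedReadPair]:
    out = []
    for i in range(0, len(reads) - 1, 2):
        a, b = reads[i], reads[i + 1]
        out.append(BarcodedReadPair(f"t{i}", a, "I" * len(a), b, "I" * len(b),
                                    "A" * 14))
    return out


class TestFindGapsAndMask:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGNNNACG", [(3, 6)]),
        ("ACGTACGT", []),
        ("NNACGNN", [(0, 2), (5, 7)]),
    ])
    def test_maximal_runs(self, seq, expected):
        assert [(g.start, g.end) for g in find_gaps(seq)] == expected

    def test_mask_region(self):
        assert mask_region("ACGTACGTACGT", (5, 8)) == "ACGTANNNACGT"

    def test_mask_merges_with_adjacent_gap(self):
        masked = mask_region("ACGNNNACGTAC", (6, 8))
        assert [(g.start, g.end) for g in find_gaps(masked)] == [(3, 8)]

    def test_empty_interval_unchanged(self):
        assert mask_region("ACGT", (2, 2)) == "ACGT"

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            mask_region("ACGT", (2, 9))


def brute_force_paths(kmers: set[str], k: int, start: str, goal: str,
                      max_len: int) -> set[str]:
    """Exhaustive recursive enumeration of start->goal paths (the oracle)."""
    results = set()

    def recurse(seq):
        if len(seq) > k and seq[-k:] == goal:
            results.add(seq)
            return
        if len(seq) >= max_len:
            return
        for b in BASES:
            nxt = seq[-k+1:] + b if k > 1 else b
            if canonical_kmer(nxt) in kmers:
                recurse(seq + b)

    recurse(start)
    return results


class TestBoundedPathSearch:
    @pytest.mark.parametrize("trial", range(8))
    def test_matches_exhaustive_dfs_on_exact_sets(self, trial):
        """On graphs of <= 1000 vertices with exact k-mer sets the engine
        must enumerate exactly the brute-force path set."""
        rng = np.random.default_rng(200 + trial)
        k = 11
        base = random_dna(rng, 400)
        # add a mutated variant to create bubbles
        variant = list(base)
        for pos in rng.integers(50, 350, size=4):
            variant[pos] = BASES[(BASES.index(variant[pos]) + 1) % 4]
        seqs = [base, "".join(variant)]
        member = _SetMembership(seqs, k)
        assert len(member._kmers) <= 1000
        start, goal = base[:k], base[-k:]
        limits = PathSearchLimits(B=10_000, P=500, F=600)
        flag, paths = bounded_path_search(member, k, start, goal, 600, limits)
        assert flag == "ok"
        expected = brute_force_paths(member._kmers, k, start, goal, 600)
        assert set(paths) == expected
        assert base in expected

    def test_branch_limit_on_dense_bubble(self, rng):
        """Three equal branches with B=2 must abort with branch_limit."""
        x, y = random_dna(rng, 40), random_dna(rng, 40)
        middles = [random_dna(rng, 20) for _ in range(3)]
        seqs = [x + m + y for m in middles]
        member = _SetMembership(seqs, 11)
        limits = PathSearchLimits(B=2, P=20, F=200)
        flag, _ = bounded_path_search(member, 11, x[:11], y[-11:], 200, limits)
        assert flag == "branch_limit"

    def test_path_limit(self, rng):
        x, y = random_dna(rng, 40), random_dna(rng, 40)
        middles = [random_dna(rng, 20) for _ in range(4)]
        seqs = [x + m + y for m in middles]
        member = _SetMembership(seqs, 11)
        limits = PathSearchLimits(B=1000, P=2, F=200)
        flag, paths = bounded_path_search(member, 11, x[:11], y[-11:], 200,
                                          limits)
        assert flag == "path_limit"


class TestFillGap:
    def make_scaffold_with_gap(self, rng, gap_len=200, total=2000):
        truth = random_dna(rng, total)
        start = (total - gap_len) // 2
        scaffold = truth[:start] + "N" * gap_len + truth[start + gap_len:]
        return truth, scaffold, Gap("s", start, start + gap_len)

    def test_masked_region_recovered_exactly(self, rng):
        truth, scaffold, gap = self.make_scaffold_with_gap(rng)
        reads = tile_reads(truth, read_len=80, step=5)
        res = fill_gap(scaffold, gap, reads, sweep=[75, 61, 51],
                       limits=PathSearchLimits())
        assert res.status == "closed"
        assert splice_fill(scaffold, res) == truth

    def test_flanks_byte_identical_after_fill(self, rng):
        truth, scaffold, gap = self.make_scaffold_with_gap(rng)
        reads = tile_reads(truth, read_len=80, step=5)
        res = fill_gap(scaffold, gap, reads, sweep=[75])
        filled = splice_fill(scaffold, res)
        assert filled[:res.left_anchor] == scaffold[:res.left_anchor]
        assert filled[len(filled) - (len(scaffold) - res.right_anchor):] == \
            scaffold[res.right_anchor:]

    def test_withheld_reads_leave_gap_open(self, rng):
        truth, scaffold, gap = self.make_scaffold_with_gap(rng)
        # only reads far away from the gap
        reads = tile_reads(truth[:500], read_len=80, step=5)
        res = fill_gap(scaffold, gap, reads, sweep=[75, 61])
        assert res.status in ("no_path", "no_start_kmer", "no_goal_kmer")
        assert res.fill is None

    def test_deterministic(self, rng):
        truth, scaffold, gap = self.make_scaffold_with_gap(rng)
        reads = tile_reads(truth, read_len=80, step=5)
        r1 = fill_gap(scaffold, gap, reads, sweep=[75, 61])
        r2 = fill_gap(scaffold, gap, reads, sweep=[75, 61])
        assert (r1.status, r1.k_used, r1.fill) == (r2.status, r2.k_used, r2.fill)

    def test_first_successful_k_wins(self, rng):
        truth, scaffold, gap = self.make_scaffold_with_gap(rng)
        reads = tile_reads(truth, read_len=80, step=5)
        res = fill_gap(scaffold, gap, reads, sweep=[75, 61, 51])
        assert res.k_used == 75
        assert 61 not in res.per_k

    def test_repeat_gap_with_tight_path_limit(self, rng):
        """A gap inside a two-copy repeat with P=1 stays open."""
        core = random_dna(rng, 300)
        v1 = list(core)
        v1[150] = {"A": "C", "C": "G", "G": "T", "T": "A"}[v1[150]]
        truth = (random_dna(rng, 300) + core + random_dna(rng, 300)
                 + "".join(v1) + random_dna(rng, 300))
        gap_start, gap_end = 400, 500  # inside the first core copy
        scaffold = truth[:gap_start] + "N" * 100 + truth[gap_end:]
        reads = tile_reads(truth, read_len=60, step=4)
        res = fill_gap(scaffold, Gap("s", gap_start, gap_end), reads,
                       sweep=[41], limits=PathSearchLimits(B=3000, P=1, F=500))
        assert res.status in ("path_limit", "ambiguous")


class TestEnrichReads:
    def test_extracted_interval_covers_gap_locus(self, rng):
        truth = random_dna(rng, 4000)
        # related reference: 1% diverged
        ref = list(truth)
        for pos in rng.integers(0, 4000, size=40):
            ref[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[ref[pos]]
        ref = "".join(ref)
        gap = Gap("s", 1900, 2100)
        scaffold = truth[:1900] + "N" * 200 + truth[2100:]
        reads = pairs_from_reads(tile_reads(truth, read_len=100, step=9))
        kept, interval = enrich_reads_for_gap(scaffold, gap, ref, reads)
        lo, hi = interval
        assert lo <= 1900 + 24 and hi >= 2100 - 24
        # enriched set keeps gap-spanning reads, discards distant ones
        assert 0 < len(kept) < len(reads)

    def test_zero_length_unaligned_region(self, rng):
        truth = random_dna(rng, 3000)
        gap = Gap("s", 1500, 1500)  # degenerate zero-length gap
        reads = pairs_from_reads(tile_reads(truth, read_len=100, step=9))
        kept, interval = enrich_reads_for_gap(truth, gap, truth, reads,
                                              pad=24)
        assert interval[1] - interval[0] == 48

    def test_unanchorable_flank_raises(self, rng):
        scaffold = random_dna(rng, 1000)
        scaffold = scaffold[:400] + "N" * 100 + scaffold[500:]
        unrelated_ref = random_dna(rng, 3000)
        reads = pairs_from_reads(tile_reads(scaffold[:400], 100, 9))
        with pytest.raises(UnanchoredError):
            enrich_reads_for_gap(scaffold, Gap("s", 400, 500), unrelated_ref,
                                 reads)


class TestFillAllGaps:
    def test_all_gaps_closed_and_monotone(self, rng):
        truth = random_dna(rng, 3000)
        scaffold = truth
        gaps = [(400, 520), (1500, 1610), (2400, 2460)]
        for s, e in gaps:
            scaffold = scaffold[:s] + "N" * (e - s) + scaffold[e:]
        reads = pairs_from_reads(tile_reads(truth, read_len=100, step=5))
        filled, rounds = fill_all_gaps(scaffold, [reads], truth,
                                       sweep=[95, 75, 61], limits=None)
        assert filled == truth
        assert len(find_gaps(filled)) == 0
        statuses = [r.status for rnd in rounds for r in rnd]
        assert statuses.count("closed") == 3

    def test_empty_bin_list_returns_unchanged(self, rng):
        scaffold = random_dna(rng, 500) + "N" * 50 + random_dna(rng, 500)
        filled, rounds = fill_all_gaps(scaffold, [], None, sweep=[61])
        assert filled == scaffold and rounds == []


class TestJoinEnds:
    def test_trimmed_circle_rejoined(self, rng):
        """Scaffold missing ~40 bp at the 5' end and ~2 kb at the 3' end of
        a circular truth is restored to a rotation of the full circle."""
        circle = random_dna(rng, 8000)
        scaffold = circle[40:-2000]
        junction = circle[-2300:] + circle[:340]
        reads = tile_reads(junction, read_len=100, step=3) + \
            tile_reads(scaffold[:300], read_len=100, step=3) + \
            tile_reads(scaffold[-300:], read_len=100, step=3)
        joined = join_ends(scaffold, reads, k=80, max_fragment=3500,
                           end_len=200)
        assert len(joined) == len(circle)
        doubled = circle + circle
        assert joined in doubled or revcomp(joined) in doubled

    def test_single_missing_base_closed(self, rng):
        circle = random_dna(rng, 3000)
        scaffold = circle[:-1]
        junction = circle[-500:] + circle[:500]
        reads = tile_reads(junction, read_len=100, step=3)
        joined = join_ends(scaffold, reads, k=80, max_fragment=3500,
                           end_len=200)
        assert len(joined) == 3000
        assert joined in circle + circle

    def test_missing_junction_reads_not_circularizable(self, rng):
        circle = random_dna(rng, 3000)
        scaffold = circle[:-100]
        reads = tile_reads(circle[500:2500], read_len=100, step=3)
        with pytest.raises(NotCircularizable):
            join_ends(scaffold, reads, k=80, end_len=200)

    def test_gap_bearing_scaffold_rejected(self, rng):
        with pytest.raises(ValueError):
            join_ends("ACGT" * 200 + "N" + "ACGT" * 200, [], k=80)


class TestCanonicalRotation:
    def test_rotation_invariance(self, rng):
        circle = random_dna(rng, 100)
        ref = circle
        outs = {canonical_rotation(circle[i:] + circle[:i], ref)
                for i in range(0, 100, 7)}
        assert outs == {circle}

    def test_reference_identity(self, rng):
        circle = random_dna(rng, 500)
        assert canonical_rotation(circle, circle) == circle

    def test_revcomp_input_same_output(self, rng):
        circle = random_dna(rng, 100)
        ref = circle
        for i in range(0, 100, 11):
            rotated = circle[i:] + circle[:i]
            assert canonical_rotation(revcomp(rotated), ref) == circle

    def test_without_reference_minimal_rotation(self, rng):
        circle = random_dna(rng, 60)
        # brute force: smallest rotation over both strands
        rots = [circle[i:] + circle[:i] for i in range(60)]
        rc = revcomp(circle)
        rots += [rc[i:] + rc[:i] for i in range(60)]
        assert canonical_rotation(circle, None) == min(rots)

    def test_sweep_must_decrease(self):
        with pytest.raises(ValueError):
            default_k_sweep(35, 125)
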