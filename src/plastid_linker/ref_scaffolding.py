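"""Reference-guided contig scaffolding with paired k-mer distance constraints.

A related reference genome is decomposed into pairs of k-mers a fixed
distance apart; each pair whose two k-mers land (uniquely) in different
contigs votes for an order/orientation/gap between those contigs.  Running
the procedure iteratively over an increasing distance schedule — feeding
each round's merged scaffolds into the next — links contigs across
progressively larger gaps, exactly the paired-k-mer "long read" scaffolding
strategy applied at distances 250 bp to 16 kb.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from plastid_linker.seq import canonical_kmer, revcomp


@dataclass
class KmerPairConstraint:
    """Two k-mers ``d`` bp apart (start-to-start) on the reference."""

    left: str
    right: str
    d: int


@dataclass
class LinkEvidence:
    """Aggregated votes for joining contig_a (in orient_a) before contig_b."""

    contig_a: str
    orient_a: str  # '+' or '-': orientation of A when placed before B
    contig_b: str
    orient_b: str
    gap: int       # estimated gap (may be <= 0)
    support: int


@dataclass
class ScaffoldLayout:
    """Ordered, oriented contigs per scaffold plus unplaced contigs."""

    scaffolds: list[list[tuple[str, str, int]]]  # (contig id, orient, gap-after)
    unplaced: list[str]


def extract_kmer_pairs(reference: str, k: int = 26, d: int = 1000,
                       step: int = 1) -> list[KmerPairConstraint]:
    """All (left, right) k-mer pairs separated by d, every ``step`` positions."""
    if step < 1:
        raise ValueError("step must be >= 1")
    pairs = []
    limit = len(reference) - d - k
    for p in range(0, limit + 1, step):
        pairs.append(KmerPairConstraint(reference[p:p + k],
                                        reference[p + d:p + d + k], d))
    return pairs


def _index_unique_kmers(contigs: Sequence[tuple[str, str]], k: int
                        ) -> dict[str, tuple[str, int, str]]:
    """canonical k-mer -> (contig id, oriented start, strand), unique only.

    ``strand`` '+' means the contig's forward text contains the k-mer as
    given; '-' means its reverse complement does.
    """
    index: dict[str, tuple[str, int, str]] = {}
    repeated: set[str] = set()
    for cid, seq in contigs:
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            canon = canonical_kmer(kmer)
            if canon in repeated:
                continue
            strand = "+" if kmer == canon else "-"
            if canon in index:
                del index[canon]
                repeated.add(canon)
            else:
                index[canon] = (cid, i, strand)
    return index


def collect_links(pairs: Sequence[KmerPairConstraint],
                  contigs: Sequence[tuple[str, str]]) -> list[LinkEvidence]:
    """Turn k-mer pair constraints into aggregated inter-contig link votes.

    Only k-mers occurring exactly once across all contigs are used.  For a
    pair landing in two different contigs, the implied layout places the
    left k-mer's contig (oriented so the k-mer reads forward) before the
    right one, with gap = d - (bases from the left k-mer start to its
    contig's 3' end) - (bases from the right contig's 5' end to the right
    k-mer start) + k ... computed start-to-start, see below.
    """
    if not pairs:
        return []
    k = len(pairs[0].left)
    index = _index_unique_kmers(contigs, k)
    lengths = {cid: len(seq) for cid, seq in contigs}
    votes: dict[tuple[str, str, str, str], list[int]] = defaultdict(list)

    for pc in pairs:
        hit_l = index.get(canonical_kmer(pc.left))
        hit_r = index.get(canonical_kmer(pc.right))
        if hit_l is None or hit_r is None:
            continue
        cid_l, pos_l, strand_l = hit_l
        cid_r, pos_r, strand_r = hit_r
        if cid_l == cid_r:
            continue
        # orientation of the contig so that the constraint k-mer reads
        # forward within it
        orient_l = strand_l if pc.left == canonical_kmer(pc.left) else _flip(strand_l)
        orient_r = strand_r if pc.right == canonical_kmer(pc.right) else _flip(strand_r)
        # start position of the k-mer in the oriented contig
        opos_l = pos_l if orient_l == "+" else lengths[cid_l] - pos_l - k
        opos_r = pos_r if orient_r == "+" else lengths[cid_r] - pos_r - k
        gap = pc.d - (lengths[cid_l] - opos_l) - opos_r
        # the gap estimate is symmetric under representation flip
        votes[_normalize_key(cid_l, orient_l, cid_r, orient_r)].append(gap)

    out = []
    for (ca, oa, cb, ob), gaps in sorted(votes.items()):
        gaps.sort()
        gap = gaps[len(gaps) // 2]
        out.append(LinkEvidence(ca, oa, cb, ob, gap, len(gaps)))
    return out


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _normalize_key(ca: str, oa: str, cb: str, ob: str) -> tuple[str, str, str, str]:
    """A->B in (oa, ob) is the same join as B->A in (flip ob, flip oa)."""
    alt = (cb, _flip(ob), ca, _flip(oa))
    fwd = (ca, oa, cb, ob)
    return min(fwd, alt)


def layout_scaffolds(evidence: Sequence[LinkEvidence], min_support: int = 5,
                     all_contig_ids: Sequence[str] = ()) -> ScaffoldLayout:
    """Greedy layout: strongest links first, one partner per contig end.

    Links below ``min_support`` are dropped; ties are broken by smaller
    absolute gap estimate, then lexicographic contig ids, so the layout is
    deterministic.  Links that would close a cycle are rejected (the
    weakest link of any cycle is never used).
    """
    links = [e for e in evidence if e.support >= min_support]
    links.sort(key=lambda e: (-e.support, abs(e.gap), e.contig_a, e.contig_b,
                              e.orient_a, e.orient_b))
    # each contig has a 'head' (5' in its + orientation) and 'tail' (3')
    used_end: set[tuple[str, str]] = set()
    joins: list[LinkEvidence] = []
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    contig_ids = set()
    for e in links:
        contig_ids.add(e.contig_a)
        contig_ids.add(e.contig_b)

    for e in links:
        end_a = (e.contig_a, "tail" if e.orient_a == "+" else "head")
        end_b = (e.contig_b, "head" if e.orient_b == "+" else "tail")
        if end_a in used_end or end_b in used_end:
            continue
        ra, rb = find(e.contig_a), find(e.contig_b)
        if ra == rb:
            continue  # would close a cycle
        used_end.add(end_a)
        used_end.add(end_b)
        parent[ra] = rb
        joins.append(e)

    # build adjacency and walk chains
    nxt: dict[tuple[str, str], tuple[str, str, int]] = {}
    prv: dict[tuple[str, str], tuple[str, str, int]] = {}
    for e in joins:
        nxt[(e.contig_a, e.orient_a)] = (e.contig_b, e.orient_b, e.gap)
        nxt[(e.contig_b, _flip(e.orient_b))] = (e.contig_a, _flip(e.orient_a), e.gap)
        prv[(e.contig_b, e.orient_b)] = (e.contig_a, e.orient_a, e.gap)
        prv[(e.contig_a, _flip(e.orient_a))] = (e.contig_b, _flip(e.orient_b), e.gap)

    placed: set[str] = set()
    scaffolds: list[list[tuple[str, str, int]]] = []
    for cid in sorted(contig_ids):
        if cid in placed:
            continue
        # walk left to the chain start
        node = (cid, "+")
        seen = {cid}
        while node in prv:
            pid, po, _ = prv[node]
            if pid in seen:
                break
            node = (pid, po)
            seen.add(pid)
        chain: list[tuple[str, str, int]] = []
        cur = node
        while True:
            placed.add(cur[0])
            if cur in nxt:
                nid, no, gap = nxt[cur]
                if nid in {c for c, _, _ in chain} or nid == cur[0]:
                    chain.append((cur[0], cur[1], 0))
                    break
                chain.append((cur[0], cur[1], gap))
                cur = (nid, no)
            else:
                chain.append((cur[0], cur[1], 0))
                break
        scaffolds.append(chain)

    unplaced = sorted(set(all_contig_ids) - placed)
    return ScaffoldLayout(scaffolds, unplaced=unplaced)


def render_scaffolds(layout: ScaffoldLayout,
                     contigs: Sequence[tuple[str, str]],
                     all_contigs_as_singletons: bool = True
                     ) -> list[tuple[str, str]]:
    """Materialize scaffold sequences; gap estimates >= 1 become that many
    'N', estimates <= 0 become a single 'N'."""
    seqs = dict(contigs)
    out: list[tuple[str, str]] = []
    placed: set[str] = set()
    for i, chain in enumerate(layout.scaffolds):
        parts = []
        for j, (cid, orient, gap) in enumerate(chain):
            placed.add(cid)
            s = seqs[cid] if orient == "+" else revcomp(seqs[cid])
            parts.append(s)
            if j < len(chain) - 1:
                parts.append("N" * max(1, gap))
        out.append((f"scaffold{i}", "".join(parts)))
    if all_contigs_as_singletons:
        n = len(out)
        for cid, seq in contigs:
            if cid not in placed:
                out.append((f"scaffold{n}", seq))
                n += 1
    return out


def iterate_distances(contigs: Sequence[tuple[str, str]], reference: str,
                      schedule: Sequence[int], k: int = 26, step: int = 1,
                      min_support: int = 5) -> list[tuple[str, str]]:
    """Re-scaffold iteratively over an increasing distance schedule.

    At each distance the current sequences are scaffolded and merged; the
    merged sequences are the input to the next distance.
    """
    if list(schedule) != sorted(set(schedule)):
        raise ValueError("schedule must be strictly increasing")
    current = list(contigs)
    for d in schedule:
        pairs = extract_kmer_pairs(reference, k=k, d=d, step=step)
        evidence = collect_links(pairs, current)
        layout = layout_scaffolds(evidence, min_support=min_support,
                                  all_contig_ids=[c for c, _ in current])
        current = render_scaffolds(layout, current)
    return current


def default_distance_schedule(max_d: int = 16_000) -> list[int]:
    """250-2,000 by 250; 2,000-9,000 by 500; 9,000-16,000 by 1,000."""
    sched = list(range(250, 2000, 250))
    sched += list(range(2000, 9000, 500))
    sched += list(range(9000, max_d + 1, 1000))
    return [d for d in sched if d <= max_d]
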