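"""Gap closure by bounded path search, per-gap read enrichment, circularization.

Scaffold gaps (N-runs) are closed by a depth-first bounded path search over
a Bloom-filter de Bruijn graph of the read k-mers, swept over a descending
list of k values; the first k that yields an acceptable path wins.  When a
gap resists closure, reads are enriched per locus: the gap flanks are
anchored to a related reference, the reference interval spanning the gap is
extracted, and only reads sharing k-mers with that interval are retained
for the next attempt.  Finally the two scaffold ends are joined through the
same path-search engine to recover the circular genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from plastid_linker.kmer_bloom import BloomFilter, build_bloom, classify_reads
from plastid_linker.reads import BarcodedReadPair
from plastid_linker.seq import canonical_kmer, revcomp

BASES = "ACGT"


@dataclass(frozen=True)
class Gap:
    """Maximal N-run ``[start, end)`` on a scaffold."""

    scaffold_id: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class PathSearchLimits:
    """Caps on the bounded path search."""

    B: int = 3000   # max branch events
    P: int = 20     # max distinct start->goal paths
    F: int = 5000   # max search length / flank slide, bp

    def __post_init__(self):
        if self.B < 1 or self.P < 1 or self.F < 1:
            raise ValueError("all path-search limits must be >= 1")


@dataclass
class GapFillResult:
    gap: Gap
    status: str                     # closed | no_start_kmer | no_goal_kmer |
                                    # branch_limit | path_limit | no_path | ambiguous
    k_used: int | None = None
    fill: str | None = None         # bases replacing scaffold[left_anchor:right_anchor]
    left_anchor: int | None = None
    right_anchor: int | None = None
    per_k: dict[int, str] = field(default_factory=dict)


def default_k_sweep(hi: int = 125, lo: int = 35) -> list[int]:
    """Descending k list: step 5 down to 95, then step 1 down to ``lo``."""
    if hi < lo:
        raise ValueError("sweep upper bound below lower bound")
    ks = list(range(hi, 95 - 1, -5)) + list(range(94, lo - 1, -1))
    return [k for k in ks if lo <= k <= hi]


def validate_sweep(sweep: Sequence[int]) -> list[int]:
    sweep = list(sweep)
    if any(b >= a for a, b in zip(sweep, sweep[1:])):
        raise ValueError("k sweep must be strictly decreasing")
    return sweep


def find_gaps(scaffold: str, scaffold_id: str = "scaffold") -> list[Gap]:
    """Maximal runs of 'N', left to right."""
    gaps = []
    i, n = 0, len(scaffold)
    while i < n:
        if scaffold[i] == "N":
            j = i
            while j < n and scaffold[j] == "N":
                j += 1
            gaps.append(Gap(scaffold_id, i, j))
            i = j
        else:
            i += 1
    return gaps


def mask_region(scaffold: str, interval: tuple[int, int]) -> str:
    """Replace ``[start, end)`` with 'N's (merges with adjacent gaps)."""
    start, end = interval
    if not 0 <= start <= end <= len(scaffold):
        raise ValueError("mask interval out of bounds")
    return scaffold[:start] + "N" * (end - start) + scaffold[end:]


# ------------------------------------------------------------ path search


class _SetMembership:
    """Exact canonical k-mer set; drop-in alternative to a Bloom filter."""

    def __init__(self, seqs: Sequence[str], k: int):
        self.k = k
        kmers = set()
        for s in seqs:
            rc = revcomp(s)
            n = len(s)
            for i in range(n - k + 1):
                fwd = s[i:i + k]
                if "N" in fwd:
                    continue
                bwd = rc[n - i - k:n - i]
                kmers.add(fwd if fwd <= bwd else bwd)
        self._kmers = kmers

    def contains_canonical(self, kmer: str) -> bool:
        return kmer in self._kmers


def bounded_path_search(member, k: int, start: str, goal: str, max_len: int,
                        limits: PathSearchLimits) -> tuple[str, list[str]]:
    """All start->goal paths in the implicit de Bruijn graph, depth-first.

    Extends one base at a time to the right; an extension exists when the
    canonical form of the next k-mer is in ``member``.  Returns
    (flag, paths): flag is 'ok', 'branch_limit' (total branch events
    exceeded B) or 'path_limit' (more than P complete paths).  Each path
    includes both the start and the goal k-mer.
    """
    branch_events = 0
    paths: list[str] = []
    # stack holds the sequence spelled so far (ending in the current k-mer)
    stack = [start]
    while stack:
        seq = stack.pop()
        cur = seq[-k:]
        if cur == goal and len(seq) > k:
            paths.append(seq)
            if len(paths) > limits.P:
                return "path_limit", paths
            continue
        if len(seq) >= max_len:
            continue
        stem = cur[1:]
        exts = [b for b in BASES
                if member.contains_canonical(canonical_kmer(stem + b))]
        if len(exts) > 1:
            # every alternative explored at a fork counts as a branch event
            branch_events += len(exts)
            if branch_events > limits.B:
                return "branch_limit", paths
        for b in exts:
            stack.append(seq + b)
    return "ok", paths


def _consensus(paths: list[str], min_identity: float = 0.95) -> str | None:
    """Column-majority consensus of equal-length paths, or None.

    Requires every pair of paths to agree on >= ``min_identity`` of
    positions and a strict majority in every column: a tied column means
    the read evidence genuinely cannot phase the locus (e.g. two repeat
    copies), and inventing a base there would silently corrupt the fill.
    """
    L = len(paths[0])
    if any(len(p) != L for p in paths):
        return None
    for i, a in enumerate(paths):
        for b in paths[i + 1:]:
            ident = sum(x == y for x, y in zip(a, b)) / L
            if ident < min_identity:
                return None
    cols = []
    for j in range(L):
        col = [p[j] for p in paths]
        counts = sorted(((col.count(b), b) for b in set(col)), reverse=True)
        if len(counts) > 1 and counts[0][0] == counts[1][0]:
            return None  # tied column: unresolvable
        cols.append(counts[0][1])
    return "".join(cols)


def _find_anchor(scaffold: str, member, k: int, gap: Gap, side: str,
                 max_slide: int) -> int | None:
    """Anchor k-mer position: slide outward from the gap edge until the
    k-mer is present in the filter (and N-free)."""
    if side == "left":
        pos = gap.start - k
        step = -1
        lo = max(0, gap.start - k - max_slide)
        while pos >= lo:
            kmer = scaffold[pos:pos + k]
            if "N" not in kmer and member.contains_canonical(canonical_kmer(kmer)):
                return pos
            pos += step
        return None
    pos = gap.end
    hi = min(len(scaffold) - k, gap.end + max_slide)
    while pos <= hi:
        kmer = scaffold[pos:pos + k]
        if "N" not in kmer and member.contains_canonical(canonical_kmer(kmer)):
            return pos
        pos += 1
    return None


def fill_gap(scaffold: str, gap: Gap, reads: Sequence[str],
             sweep: Sequence[int], limits: PathSearchLimits | None = None,
             fpr: float = 0.001,
             membership_factory: Callable[[int], object] | None = None
             ) -> GapFillResult:
    """Attempt to close one gap with a descending k sweep.

    For each k a Bloom filter of read k-mers is built (or fetched from
    ``membership_factory``); start/goal k-mers are taken immediately beside
    the gap, sliding outward up to F bases when absent from the filter.
    The first k producing a unique path (or an acceptable consensus of up
    to P equal-length paths) closes the gap.  Per-k failure statuses are
    recorded; the overall status on failure is the last k's status.
    """
    limits = limits or PathSearchLimits()
    sweep = validate_sweep(sweep)
    result = GapFillResult(gap, "no_path")
    for k in sweep:
        if gap.start < k or gap.end + k > len(scaffold):
            result.per_k[k] = "no_start_kmer" if gap.start < k else "no_goal_kmer"
            result.status = result.per_k[k]
            continue
        if membership_factory is not None:
            member = membership_factory(k)
        else:
            member = build_bloom([s for s in reads if len(s) >= k], k, fpr)
        ls = _find_anchor(scaffold, member, k, gap, "left", limits.F)
        if ls is None:
            result.per_k[k] = "no_start_kmer"
            result.status = "no_start_kmer"
            continue
        rs = _find_anchor(scaffold, member, k, gap, "right", limits.F)
        if rs is None:
            result.per_k[k] = "no_goal_kmer"
            result.status = "no_goal_kmer"
            continue
        start = scaffold[ls:ls + k]
        goal = scaffold[rs:rs + k]
        max_len = limits.F + (rs - ls) + k
        flag, paths = bounded_path_search(member, k, start, goal, max_len, limits)
        if flag in ("branch_limit", "path_limit"):
            result.per_k[k] = flag
            result.status = flag
            continue
        if not paths:
            result.per_k[k] = "no_path"
            result.status = "no_path"
            continue
        if len(paths) == 1:
            fill = paths[0]
        else:
            cons = _consensus(paths)
            if cons is None:
                result.per_k[k] = "ambiguous"
                result.status = "ambiguous"
                # a smaller k only collapses more repeat context; once the
                # evidence is ambiguous the sweep cannot recover
                break
            fill = cons
        result.per_k[k] = "closed"
        result.status = "closed"
        result.k_used = k
        result.fill = fill
        result.left_anchor = ls
        result.right_anchor = rs + k
        return result
    return result


def splice_fill(scaffold: str, result: GapFillResult) -> str:
    """Apply a closed GapFillResult to the scaffold."""
    if result.status != "closed":
        return scaffold
    return (scaffold[:result.left_anchor] + result.fill
            + scaffold[result.right_anchor:])


# ------------------------------------------------------------ enrichment


class UnanchoredError(RuntimeError):
    """A gap flank could not be anchored to the reference."""


def _reference_index(reference: str, k: int) -> dict[str, list[tuple[int, str]]]:
    index: dict[str, list[tuple[int, str]]] = {}
    rc = revcomp(reference)
    n = len(reference)
    for i in range(n - k + 1):
        fwd = reference[i:i + k]
        bwd = rc[n - i - k:n - i]
        if fwd <= bwd:
            index.setdefault(fwd, []).append((i, "+"))
        else:
            index.setdefault(bwd, []).append((i, "-"))
    return index


def _anchor_flank(flank: str, ref_index, k: int, want: str,
                  prefer: str) -> int | None:
    """Map the gap-side end of a flank onto the reference.

    ``want`` selects the orientation ('+': scaffold co-linear with the
    reference).  For a left flank returns the reference coordinate of the
    base just right of the flank; for a right flank, the coordinate of the
    flank's first base.  Prefers the seed closest to the gap.
    """
    n = len(flank)
    if n < k:
        return None
    offsets = range(n - k, -1, -1) if prefer == "right" else range(0, n - k + 1)
    for fo in offsets:
        kmer = flank[fo:fo + k]
        if "N" in kmer:
            continue
        hits = ref_index.get(canonical_kmer(kmer))
        if not hits or len(hits) != 1:
            continue
        pos, strand = hits[0]
        fwd_match = (kmer == canonical_kmer(kmer)) == (strand == "+")
        orient = "+" if fwd_match else "-"
        if orient != want:
            continue
        if want == "+":
            if prefer == "right":   # left flank: coordinate after flank end
                return pos + k + (n - (fo + k))
            return pos - fo         # right flank: coordinate of flank start
        # scaffold maps to the reference minus strand
        if prefer == "right":       # left flank end maps leftward on ref
            return pos - (n - (fo + k))
        return pos + k + fo         # right flank start, on minus strand
    return None


def enrich_reads_for_gap(scaffold: str, gap: Gap, reference: str,
                         reads: Sequence[BarcodedReadPair], flank: int = 500,
                         pad: int = 24, k: int = 25, fpr: float = 0.001,
                         min_share: float = 0.15
                         ) -> tuple[list[BarcodedReadPair], tuple[int, int]]:
    """Keep only reads likely to span the gap locus.

    The gap flanks are anchored to the related reference by unique exact
    k-mer seeds; the reference interval strictly between the anchored flank
    ends, widened by ``pad`` on each side, is extracted; a Bloom filter of
    that interval classifies the reads.  Returns (enriched pairs, interval).
    Raises :class:`UnanchoredError` when a flank has no unique seed.
    """
    left = scaffold[max(0, gap.start - flank):gap.start]
    right = scaffold[gap.end:gap.end + flank]
    # keep only the N-free stretch adjacent to the gap
    if "N" in left:
        left = left[left.rfind("N") + 1:]
    if "N" in right:
        npos = right.find("N")
        right = right[:npos]
    ref_index = _reference_index(reference, k)
    interval = None
    for want in ("+", "-"):
        le = _anchor_flank(left, ref_index, k, want, "right")
        rs = _anchor_flank(right, ref_index, k, want, "left")
        if le is None or rs is None:
            continue
        lo, hi = (le, rs) if want == "+" else (rs, le)
        if hi < lo:
            mid = (lo + hi) // 2
            lo = hi = mid
        interval = (max(0, lo - pad), min(len(reference), hi + pad))
        break
    if interval is None:
        raise UnanchoredError(f"gap {gap.start}-{gap.end}: flank not anchorable")
    extracted = reference[interval[0]:interval[1]]
    if len(extracted) < k:
        raise UnanchoredError(f"gap {gap.start}-{gap.end}: extracted interval "
                              f"shorter than k")
    bf = build_bloom([extracted], k, fpr)
    return classify_reads(reads, bf, min_share), interval


# ------------------------------------------------------------ whole-scaffold


def fill_all_gaps(scaffold: str,
                  bins: Sequence[Sequence[BarcodedReadPair]],
                  reference: str | None,
                  sweep: Sequence[int],
                  limits: PathSearchLimits | None = None,
                  fpr: float = 0.001,
                  enrich_kwargs: dict | None = None
                  ) -> tuple[str, list[list[GapFillResult]]]:
    """Close gaps over successive rounds of progressively larger read sets.

    Round 1 uses the first (most selective) bin without enrichment; each
    later round applies per-gap read enrichment against the reference with
    the successive bins.  Closed gaps are spliced immediately (right to
    left, so coordinates stay valid) and never reopen.
    """
    limits = limits or PathSearchLimits()
    sweep = validate_sweep(sweep)
    enrich_kwargs = enrich_kwargs or {}
    rounds: list[tuple[int, bool]] = [(0, False)]
    if reference is not None:
        rounds += [(i, True) for i in range(len(bins))]
    all_results: list[list[GapFillResult]] = []

    for bin_idx, enriched in rounds:
        if bin_idx >= len(bins):
            break
        gaps = find_gaps(scaffold)
        if not gaps:
            break
        pairs = list(bins[bin_idx])
        round_results: list[GapFillResult] = []
        member_cache: dict[int, object] = {}
        base_seqs = None

        def plain_factory(k: int):
            nonlocal base_seqs
            if k not in member_cache:
                if base_seqs is None:
                    base_seqs = [s for p in pairs for s in (p.seq1, p.seq2)]
                member_cache[k] = build_bloom(
                    [s for s in base_seqs if len(s) >= k], k, fpr)
            return member_cache[k]

        for gap in reversed(gaps):
            if enriched:
                try:
                    enriched_pairs, _ = enrich_reads_for_gap(
                        scaffold, gap, reference, pairs, fpr=fpr,
                        **enrich_kwargs)
                except UnanchoredError:
                    enriched_pairs = pairs
                seqs = [s for p in enriched_pairs for s in (p.seq1, p.seq2)]
                res = fill_gap(scaffold, gap, seqs, sweep, limits, fpr)
            else:
                res = fill_gap(scaffold, gap, [], sweep, limits, fpr,
                               membership_factory=plain_factory)
            round_results.append(res)
            if res.status == "closed":
                scaffold = splice_fill(scaffold, res)
        round_results.reverse()
        all_results.append(round_results)

    return scaffold, all_results


# ------------------------------------------------------------ circularization


class NotCircularizable(RuntimeError):
    """No unique read-supported path connects the scaffold ends."""


def join_ends(scaffold: str, reads: Sequence[str],
              k: int | Sequence[int] = 80,
              max_fragment: int = 3500, end_len: int = 200,
              limits: PathSearchLimits | None = None, fpr: float = 0.001
              ) -> str:
    """Join the 3' end of a gap-free scaffold back to its 5' end.

    The two scaffold ends act as a pseudo read pair; the same bounded path
    search walks from the last k-mer of the 3' end to the first k-mer of
    the 5' end through the read k-mer filter, within ``max_fragment``
    bases.  On a unique connection (or an acceptable consensus) the
    inter-end bases are appended and the sequence is circular.

    ``k`` may be a single size or a descending sweep: a junction that
    crosses a near-identical repeat can only be phased when k exceeds the
    longest stretch identical between the repeat copies, so trying larger
    k first and falling back mirrors the gap-filling sweep.  Raises
    :class:`NotCircularizable` when every k fails.
    """
    limits = limits or PathSearchLimits()
    if "N" in scaffold:
        raise ValueError("scaffold must be gap-free before circularization")
    ks = [k] if isinstance(k, int) else validate_sweep(k)
    if len(scaffold) < 2 * end_len:
        raise ValueError("scaffold shorter than twice end_len")
    failures = {}
    for kk in ks:
        if kk > end_len:
            failures[kk] = "k exceeds end_len"
            continue
        member = build_bloom([s for s in reads if len(s) >= kk], kk, fpr)
        # slide inward over the end regions until anchors are in the filter
        ls = None
        for off in range(end_len - kk + 1):
            pos = len(scaffold) - kk - off
            if member.contains_canonical(canonical_kmer(scaffold[pos:pos + kk])):
                ls = pos
                break
        gs = None
        for off in range(end_len - kk + 1):
            if member.contains_canonical(canonical_kmer(scaffold[off:off + kk])):
                gs = off
                break
        if ls is None or gs is None:
            failures[kk] = "end k-mers absent from read set"
            continue
        start = scaffold[ls:ls + kk]
        goal = scaffold[gs:gs + kk]
        flag, paths = bounded_path_search(member, kk, start, goal,
                                          max_fragment + 2 * kk, limits)
        if flag != "ok" or len(paths) == 0:
            failures[kk] = f"path search: {flag}, {len(paths)} paths"
            continue
        if len(paths) > 1:
            cons = _consensus(paths)
            if cons is None:
                failures[kk] = f"{len(paths)} conflicting paths"
                continue
            fill = cons
        else:
            fill = paths[0]
        inner = fill[kk:-kk]
        # the circle keeps scaffold[gs:ls+kk] plus the inter-end bases
        return scaffold[gs:ls + kk] + inner
    raise NotCircularizable("; ".join(f"k={kk}: {why}"
                                      for kk, why in failures.items()))


def canonical_rotation(circular: str, reference: str | None = None,
                       k: int = 31) -> str:
    """Rotate (and complement if needed) a circular sequence canonically.

    If the reference's first k-mer occurs exactly once on one strand of the
    circle, that occurrence is rotated to position 0; otherwise the
    lexicographically minimal rotation over both strands is returned.
    """
    n = len(circular)
    k = min(k, n)
    if reference is not None and len(reference) >= k:
        probe = reference[:k]
        for strand in (circular, revcomp(circular)):
            doubled = strand + strand[:k - 1]
            first = doubled.find(probe)
            if first != -1 and doubled.find(probe, first + 1) == -1:
                return strand[first:] + strand[:first]
    fwd = _least_rotation(circular)
    bwd = _least_rotation(revcomp(circular))
    return min(fwd, bwd)


def _least_rotation(s: str) -> str:
    """Booth's algorithm: lexicographically minimal rotation."""
    ss = s + s
    f = [-1] * len(ss)
    least = 0
    for j in range(1, len(ss)):
        c = ss[j]
        i = f[j - least - 1]
        while i != -1 and c != ss[least + i + 1]:
            if c < ss[least + i + 1]:
                least = j - i - 1
            i = f[i]
        if c != ss[least + i + 1]:
            if c < ss[least]:
                least = j
            f[j - least] = -1
        else:
            f[j - least] = i + 1
    return s[least % len(s):] + s[:least % len(s)]
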