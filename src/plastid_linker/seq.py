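"""Low-level nucleotide sequence helpers: reverse complement, canonical k-mers."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-preserving)."""
    return seq.translate(_COMP)[::-1]


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMP)[::-1]
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int):
    """Yield all length-k windows of ``seq`` that are free of ambiguous bases."""
    n = len(seq)
    # track rightmost non-ACGT position to skip windows containing it
    last_bad = -1
    for i, c in enumerate(seq):
        if c not in "ACGT":
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            yield seq[i - k + 1 : i + 1]


def iter_canonical_kmers(seq: str, k: int):
    for kmer in iter_kmers(seq, k):
        yield canonical_kmer(kmer)


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so position ``offset`` becomes position 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]
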