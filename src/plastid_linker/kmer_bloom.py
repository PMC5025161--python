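"""Bloom filter over canonical k-mers and read classification against it.

Used for locus-targeted read enrichment: build a filter from a reference
interval believed to span a scaffold gap, then keep only read pairs where
at least one mate shares a sufficient fraction of its k-mers with the
filter.  Guarantees: no false negatives ever; false-positive rate is set by
the sizing formula m = ceil(-n ln f / (ln 2)^2), h = round((m/n) ln 2).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from plastid_linker.reads import BarcodedReadPair
from plastid_linker.seq import canonical_kmer, revcomp

_LN2 = math.log(2.0)


def _hash_pair(data: bytes) -> tuple[int, int]:
    """Two independent 64-bit hashes from one keyed blake2b digest."""
    d = hashlib.blake2b(data, digest_size=16).digest()
    return int.from_bytes(d[:8], "little"), int.from_bytes(d[8:], "little")


@dataclass
class BloomFilter:
    """Canonical k-mer membership filter with double hashing."""

    k: int
    bits: int
    hashes: int
    inserted: int = 0
    target_fpr: float = 0.001
    _array: bytearray = field(default_factory=bytearray, repr=False)

    @classmethod
    def sized_for(cls, n: int, k: int, target_fpr: float) -> "BloomFilter":
        n = max(1, n)
        m = math.ceil(-n * math.log(target_fpr) / (_LN2 ** 2))
        h = max(1, round((m / n) * _LN2))
        bf = cls(k=k, bits=m, hashes=h, inserted=0, target_fpr=target_fpr)
        bf._array = bytearray((m + 7) // 8)
        return bf

    def _positions(self, kmer: str):
        h1, h2 = _hash_pair(kmer.encode())
        m = self.bits
        for i in range(self.hashes):
            yield (h1 + i * h2) % m

    def add(self, kmer: str) -> None:
        kmer = canonical_kmer(kmer)
        for pos in self._positions(kmer):
            self._array[pos >> 3] |= 1 << (pos & 7)
        self.inserted += 1

    def __contains__(self, kmer: str) -> bool:
        kmer = canonical_kmer(kmer)
        arr = self._array
        for pos in self._positions(kmer):
            if not arr[pos >> 3] & (1 << (pos & 7)):
                return False
        return True

    def contains_canonical(self, kmer: str) -> bool:
        """Membership for a k-mer already in canonical form (no recompute)."""
        arr = self._array
        for pos in self._positions(kmer):
            if not arr[pos >> 3] & (1 << (pos & 7)):
                return False
        return True

    # ---------------------------------------------------------- persistence

    def save(self, path) -> None:
        header = json.dumps({"k": self.k, "bits": self.bits,
                             "hashes": self.hashes, "inserted": self.inserted,
                             "target_fpr": self.target_fpr}).encode()
        with open(path, "wb") as fh:
            fh.write(len(header).to_bytes(4, "little"))
            fh.write(header)
            fh.write(bytes(self._array))

    @classmethod
    def load(cls, path) -> "BloomFilter":
        with open(path, "rb") as fh:
            hlen = int.from_bytes(fh.read(4), "little")
            meta = json.loads(fh.read(hlen).decode())
            arr = bytearray(fh.read())
        bf = cls(k=meta["k"], bits=meta["bits"], hashes=meta["hashes"],
                 inserted=meta["inserted"], target_fpr=meta["target_fpr"])
        bf._array = arr
        return bf


def build_bloom(seqs: Iterable[str], k: int = 25,
                target_fpr: float = 0.001) -> BloomFilter:
    """Insert all canonical k-mers of all sequences into a sized filter.

    Sequences shorter than k are skipped.  The filter is sized from the
    total k-mer window count (an upper bound on distinct k-mers), which
    keeps the realized false-positive rate at or below the target.
    """
    seqs = list(seqs)
    n_windows = sum(max(0, len(s) - k + 1) for s in seqs)
    bf = BloomFilter.sized_for(n_windows, k, target_fpr)
    n_short = 0
    for seq in seqs:
        if len(seq) < k:
            n_short += 1
            continue
        rc = revcomp(seq)
        n = len(seq)
        for i in range(n - k + 1):
            fwd = seq[i:i + k]
            bwd = rc[n - i - k:n - i]
            canon = fwd if fwd <= bwd else bwd
            for pos in bf._positions(canon):
                bf._array[pos >> 3] |= 1 << (pos & 7)
            bf.inserted += 1
    if n_short:
        import warnings
        warnings.warn(f"{n_short} sequence(s) shorter than k={k} skipped",
                      stacklevel=2)
    return bf


def read_kmer_share(seq: str, bf: BloomFilter) -> float:
    """Fraction of a read's k-mers present in the filter (0 if too short)."""
    k = bf.k
    n = len(seq)
    if n < k:
        return 0.0
    rc = revcomp(seq)
    hits = total = 0
    for i in range(n - k + 1):
        fwd = seq[i:i + k]
        bwd = rc[n - i - k:n - i]
        canon = fwd if fwd <= bwd else bwd
        total += 1
        if bf.contains_canonical(canon):
            hits += 1
    return hits / total


def classify_reads(reads: Sequence[BarcodedReadPair], bf: BloomFilter,
                   min_share: float = 0.15) -> list[BarcodedReadPair]:
    """Keep pairs where either mate shares >= ``min_share`` of its k-mers
    with the filter; pairs are kept intact so gap-spanning mates survive."""
    kept = []
    for pair in reads:
        if (read_kmer_share(pair.seq1, bf) >= min_share
                or read_kmer_share(pair.seq2, bf) >= min_share):
            kept.append(pair)
    return kept
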