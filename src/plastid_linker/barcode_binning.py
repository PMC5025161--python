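"""Index-multiplicity counting and threshold bins.

High-multiplicity barcodes are enriched for high-copy organelle DNA, so
filtering read pairs into bins by the number of pairs their index carries
("at least 1,000 / 3,000 / 5,000 associated pairs" style thresholds) yields
progressively purer, smaller subsets that simplify the downstream de Bruijn
graphs.  The counting unit throughout is the read *pair*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from plastid_linker.reads import BarcodedReadPair


@dataclass
class IndexCountTable:
    """Read-pair multiplicity per fully sequenced (N-free) index."""

    counts: dict[str, int] = field(default_factory=dict)
    total_pairs: int = 0
    excluded_ambiguous: int = 0

    def threshold_for_fraction(self, fraction: float) -> int:
        """Smallest threshold whose bin captures at most ``fraction`` of pairs.

        Mirrors how multiplicity cut-offs are read off the index-multiplicity
        distribution: scan candidate thresholds (the distinct counts,
        descending bins) and return the lowest count ``t`` such that pairs
        from indices with count >= t make up <= ``fraction`` of all pairs.
        """
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if not self.counts:
            return 1
        distinct = sorted(set(self.counts.values()), reverse=True)
        cum = 0
        best = distinct[0]  # most selective nonempty bin as fallback
        for t in distinct:
            cum += sum(c for c in self.counts.values() if c == t)
            if self.total_pairs and cum / self.total_pairs <= fraction:
                best = t
            else:
                break
        return best


@dataclass
class ReadBin:
    """All read pairs whose index has at least ``threshold`` pairs."""

    threshold: int
    indices: set[str]
    pairs: list[BarcodedReadPair]
    fraction_of_total: float


def count_index_multiplicity(reads: Iterable[BarcodedReadPair]) -> IndexCountTable:
    """Count read pairs per index; indices containing 'N' are excluded and tallied."""
    table = IndexCountTable()
    for pair in reads:
        if not pair.barcode:
            raise ValueError(f"read pair {pair.name!r} lacks a barcode")
        table.total_pairs += 1
        if "N" in pair.barcode:
            table.excluded_ambiguous += 1
        else:
            table.counts[pair.barcode] = table.counts.get(pair.barcode, 0) + 1
    return table


def bin_reads(reads: Sequence[BarcodedReadPair], table: IndexCountTable,
              threshold: int) -> ReadBin:
    """Extract the bin of pairs whose index multiplicity is >= ``threshold``.

    The threshold is inclusive and pairs are kept in input order.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    indices = {idx for idx, c in table.counts.items() if c >= threshold}
    pairs = [p for p in reads if p.barcode in indices]
    frac = len(pairs) / table.total_pairs if table.total_pairs else 0.0
    return ReadBin(threshold, indices, pairs, frac)


@dataclass
class HistogramRow:
    threshold: int
    n_indices: int
    n_pairs: int
    fraction_of_pairs: float


def multiplicity_histogram(table: IndexCountTable,
                           thresholds: Sequence[int] = ()
                           ) -> tuple[list[int], list[HistogramRow]]:
    """Ascending per-index counts plus a summary row per threshold."""
    ascending = sorted(table.counts.values())
    rows = []
    for t in thresholds:
        hit = [c for c in table.counts.values() if c >= t]
        n_pairs = sum(hit)
        frac = n_pairs / table.total_pairs if table.total_pairs else 0.0
        rows.append(HistogramRow(t, len(hit), n_pairs, frac))
    return ascending, rows
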