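"""Read-pair container and FASTQ/FASTA I/O with the ``BX:Z:`` barcode dialect.

Barcodes travel in the FASTQ header comment as ``BX:Z:<14-mer>`` on both
mates.  An alternate ingest mode treats the first 14 bases of read 1 as the
index and trims them off.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

BARCODE_LEN = 14


@dataclass
class BarcodedReadPair:
    """One sequenced fragment insert: two reads + qualities + 14 bp index."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    barcode: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read/quality length mismatch in record {self.name!r}")


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse a FASTA file into (name, sequence) tuples."""
    records = []
    name, chunks = None, []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.upper())
        if name is not None:
            records.append((name, "".join(chunks)))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------- FASTQ


def _fastq_records(fh: TextIO) -> Iterator[tuple[str, str, str, str]]:
    """Yield (id, comment, seq, qual) from a 4-line FASTQ stream."""
    while True:
        header = fh.readline()
        if not header:
            return
        header = header.rstrip("\n")
        if not header.startswith("@"):
            raise ValueError(f"malformed FASTQ header: {header!r}")
        seq = fh.readline().rstrip("\n")
        plus = fh.readline()
        qual = fh.readline().rstrip("\n")
        if not plus.startswith("+"):
            raise ValueError(f"malformed FASTQ record at {header!r}")
        if len(seq) != len(qual):
            raise ValueError(f"sequence/quality length mismatch at {header!r}")
        fields = header[1:].split(None, 1)
        rid = fields[0]
        comment = fields[1] if len(fields) > 1 else ""
        yield rid, comment, seq, qual


def _barcode_from_comment(comment: str) -> str | None:
    for tok in comment.split():
        if tok.startswith("BX:Z:"):
            return tok[5:]
    return None


def read_paired_fastq(path1, path2, barcode_mode: str = "comment") -> Iterator[BarcodedReadPair]:
    """Stream read pairs from two mate files.

    barcode_mode 'comment' reads ``BX:Z:`` tags; 'inline' takes the first 14
    bases of read 1 as the index and trims them (and their qualities).
    """
    with _open_text(path1) as f1, _open_text(path2) as f2:
        for (id1, c1, s1, q1), (id2, c2, s2, q2) in zip(
            _fastq_records(f1), _fastq_records(f2), strict=True
        ):
            yield _make_pair(id1, c1, s1, q1, s2, q2, barcode_mode)


def read_interleaved_fastq(path, barcode_mode: str = "comment") -> Iterator[BarcodedReadPair]:
    with _open_text(path) as fh:
        it = _fastq_records(fh)
        for rec1 in it:
            try:
                rec2 = next(it)
            except StopIteration:
                raise ValueError(f"odd record count in interleaved FASTQ at {rec1[0]!r}")
            id1, c1, s1, q1 = rec1
            _, _, s2, q2 = rec2
            yield _make_pair(id1, c1, s1, q1, s2, q2, barcode_mode)


def _make_pair(rid, comment, s1, q1, s2, q2, barcode_mode) -> BarcodedReadPair:
    if barcode_mode == "inline":
        barcode = s1[:BARCODE_LEN]
        s1, q1 = s1[BARCODE_LEN:], q1[BARCODE_LEN:]
    else:
        barcode = _barcode_from_comment(comment)
        if barcode is None:
            raise ValueError(f"read pair {rid!r} lacks a BX:Z: barcode tag")
    return BarcodedReadPair(rid, s1, q1, s2, q2, barcode)


def write_paired_fastq(path1, path2, pairs: Iterable[BarcodedReadPair]) -> None:
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for p in pairs:
            tag = f"BX:Z:{p.barcode}"
            f1.write(f"@{p.name}/1 {tag}\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.name}/2 {tag}\n{p.seq2}\n+\n{p.qual2}\n")


def write_interleaved_fastq(path, pairs: Iterable[BarcodedReadPair]) -> None:
    with _open_text(path, "wt") as fh:
        for p in pairs:
            tag = f"BX:Z:{p.barcode}"
            fh.write(f"@{p.name}/1 {tag}\n{p.seq1}\n+\n{p.qual1}\n")
            fh.write(f"@{p.name}/2 {tag}\n{p.seq2}\n+\n{p.qual2}\n")
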