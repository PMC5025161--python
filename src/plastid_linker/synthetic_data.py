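"""Synthetic genomes and barcoded linked reads.

Emulates a linked-read (GEM-partitioned) library over a small circular
high-copy organelle genome plus a low-copy nuclear background:

* the organelle genome carries a planted two-copy inverted repeat whose
  copies differ at a fixed number of substitutions;
* long fragments are partitioned into barcoded GEMs, with barcode reuse
  (barcodes drawn with replacement from a finite pool);
* reads-per-fragment is gamma-Poisson (negative binomial), so per-index
  read-pair counts are overdispersed;
* organelle molecules are at high molar excess, so a GEM that captures
  organelle DNA typically captures a burst of several organelle fragments.
  This co-localization is what makes high-multiplicity indices
  organelle-enriched, the property the binning stage exploits;
* 2 x read_length pairs with independent substitution errors, and a small
  probability that an emitted index contains an ambiguous base.

Every emitted pair has exactly one ground-truth row (source genome,
fragment, barcode, coordinates, strand).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from plastid_linker.reads import BarcodedReadPair, write_paired_fastq, write_fasta
from plastid_linker.seq import revcomp

BASES = "ACGT"


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Parameters of the linked-read simulation.

    Lengths are in bp, rates are per-base probabilities.  ``copy_ratio`` is
    the organelle:nuclear genome-copy ratio (plastids are present at a few
    hundred copies per cell).  ``organelle_burst`` is the mean number of
    extra organelle fragments co-captured by a GEM whose droplet contains
    organelle DNA; it models the molar excess of small plastid molecules.
    """

    seed: int = 0
    organelle_length: int = 30_000
    nuclear_length: int = 1_000_000
    copy_ratio: float = 200.0
    ir_length: int = 440
    ir_mismatches: int = 3
    barcode_pool: int = 5_000
    frag_len_median: int = 20_000
    frag_len_sigma: float = 0.55
    frags_per_barcode_mean: float = 1.5
    organelle_burst: float = 5.0
    reads_per_fragment_dispersion: float = 0.4
    total_pairs: int = 200_000
    read_length: int = 125
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    error_rate: float = 0.002
    n_barcode_rate: float = 0.001
    related_divergence: float = 0.01

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("organelle_length", "barcode_pool", "frag_len_median",
                     "read_length", "total_pairs"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.nuclear_length < 0:
            raise ConfigError("nuclear_length must be >= 0")
        for name in ("error_rate", "n_barcode_rate", "related_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.ir_length < 0:
            raise ConfigError("ir_length must be >= 0")
        if self.ir_length >= self.organelle_length / 4:
            raise ConfigError("ir_length must be < organelle_length / 4")
        if self.ir_mismatches < 0 or self.ir_mismatches > self.ir_length:
            raise ConfigError("ir_mismatches must be in [0, ir_length]")
        if self.read_length > self.frag_len_median:
            raise ConfigError("read_length must be <= frag_len_median")
        if self.copy_ratio <= 0:
            raise ConfigError("copy_ratio must be > 0")
        if self.frags_per_barcode_mean <= 0:
            raise ConfigError("frags_per_barcode_mean must be > 0")
        if self.reads_per_fragment_dispersion <= 0:
            raise ConfigError("reads_per_fragment_dispersion must be > 0")
        if self.organelle_burst < 0:
            raise ConfigError("organelle_burst must be >= 0")
        if self.frag_len_sigma <= 0:
            raise ConfigError("frag_len_sigma must be > 0")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class ReferenceSet:
    """Simulated source genomes: one circular organelle, linear nuclear."""

    organelle: str
    nuclear: list[str]
    ir_coords: tuple[tuple[int, int], tuple[int, int]] | None

    def write_fasta(self, path) -> None:
        records = [("organelle", self.organelle)]
        records += [(f"nuclear{i}", s) for i, s in enumerate(self.nuclear)]
        write_fasta(path, records)


@dataclass
class TruthRow:
    pair_id: str
    source: str
    fragment_id: int
    barcode: str
    start1: int
    start2: int
    strand: str


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def __len__(self):
        return len(self.rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pair_id\tsource\tfragment_id\tbarcode\tstart1\tstart2\tstrand\n")
            for r in self.rows:
                fh.write(f"{r.pair_id}\t{r.source}\t{r.fragment_id}\t{r.barcode}"
                         f"\t{r.start1}\t{r.start2}\t{r.strand}\n")

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        rows = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                pid, src, fid, bc, s1, s2, strand = line.rstrip("\n").split("\t")
                rows.append(TruthRow(pid, src, int(fid), bc, int(s1), int(s2), strand))
        return cls(rows)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def _plant_mismatches(copy2: list[str], m: int, rng: np.random.Generator) -> None:
    """Substitute ``m`` evenly spaced positions of the second IR copy.

    Even spacing keeps every identical stretch between two differences well
    below the largest k used downstream, so the two copies can be phased by
    k-mer context during gap filling — mirroring the short, nearly identical
    conifer plastid IR.
    """
    L = len(copy2)
    for i in range(m):
        pos = round((i + 1) * L / (m + 1))
        pos = min(pos, L - 1)
        old = copy2[pos]
        choices = [b for b in BASES if b != old]
        copy2[pos] = choices[int(rng.integers(0, 3))]


def generate_genomes(config: SimConfig) -> ReferenceSet:
    """Generate the circular organelle (with planted IR) and nuclear background.

    Deterministic for a fixed seed.  The second IR copy equals the reverse
    complement of the first except at exactly ``ir_mismatches`` positions;
    all other sequence is i.i.d. uniform over A/C/G/T.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    L = config.organelle_length
    organelle = list(_random_seq(rng, L))
    ir_coords = None
    if config.ir_length > 0:
        ir = config.ir_length
        # two non-overlapping, origin-avoiding intervals
        s1 = int(rng.integers(int(0.10 * L), int(0.35 * L)))
        s2 = int(rng.integers(int(0.55 * L), int(0.80 * L) - ir))
        copy1 = organelle[s1:s1 + ir]
        copy2 = list(revcomp("".join(copy1)))
        _plant_mismatches(copy2, config.ir_mismatches, rng)
        organelle[s2:s2 + ir] = copy2
        # make the repeat exactly maximal: a complementary base just outside
        # either copy would extend it by chance
        comp = dict(zip("ACGT", "TGCA"))
        for edge, partner in (((s1 - 1), s2 + ir), ((s1 + ir), s2 - 1)):
            if 0 <= edge < L and 0 <= partner < L:
                banned = comp[organelle[partner]]
                if organelle[edge] == banned:
                    allowed = [b for b in BASES if b != banned]
                    organelle[edge] = allowed[int(rng.integers(0, 3))]
        ir_coords = ((s1, s1 + ir), (s2, s2 + ir))
    nuclear = []
    if config.nuclear_length > 0:
        nuclear.append(_random_seq(rng, config.nuclear_length))
    return ReferenceSet("".join(organelle), nuclear, ir_coords)


def mutate_reference(genome: str, divergence: float, seed: int,
                     indels: bool = False) -> str:
    """Copy of ``genome`` with i.i.d. substitutions at the given rate.

    A surrogate for the related-species reference used to guide scaffolding
    (plastid genomes of congeneric species share ~99% identity).  No indels
    by default; ``indels=True`` additionally applies small (1-3 bp)
    insertions/deletions at one tenth of the substitution rate.
    """
    if not 0.0 <= divergence < 0.1:
        raise ConfigError("related_divergence must be in [0, 0.1)")
    if divergence == 0 and not indels:
        return genome
    rng = np.random.default_rng([seed, 3])
    arr = np.frombuffer(genome.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < divergence)[0]
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = base_codes[base_codes != arr[i]]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    seq = arr.tobytes().decode()
    if indels:
        out, i = [], 0
        indel_rate = divergence / 10
        while i < len(seq):
            r = rng.random()
            if r < indel_rate / 2:  # deletion
                i += int(rng.integers(1, 4))
            elif r < indel_rate:  # insertion
                out.append(seq[i])
                out.append(_random_seq(rng, int(rng.integers(1, 4))))
                i += 1
            else:
                out.append(seq[i])
                i += 1
        seq = "".join(out)
    return seq


def _barcode_pool(rng: np.random.Generator, n: int, length: int = 14) -> list[str]:
    pool, seen = [], set()
    while len(pool) < n:
        bc = _random_seq(rng, length)
        if bc not in seen:
            seen.add(bc)
            pool.append(bc)
    return pool


def _quality_string(read_length: int) -> str:
    """Constant Q37 with a linear decay to Q12 over the final 15 cycles."""
    quals = [37] * read_length
    tail = min(15, read_length)
    for j in range(tail):  # linear ramp: positions L-tail .. L-1 go 37 -> 12
        quals[read_length - tail + j] = round(37 - (37 - 12) * (j + 1) / tail)
    return "".join(chr(q + 33) for q in quals)


@dataclass
class _Fragment:
    source: str       # 'organelle' or 'nuclear<i>'
    src_len: int
    circular: bool
    start: int
    length: int
    barcode: str
    n_pairs: int


def _draw_fragments(refs: ReferenceSet, config: SimConfig,
                    rng: np.random.Generator, pool: list[str],
                    n_gems: int) -> list[_Fragment]:
    """Plan one batch of GEMs worth of fragments with their read budgets."""
    w_org = config.copy_ratio * len(refs.organelle)
    w_nuc = float(sum(len(s) for s in refs.nuclear))
    p_org = w_org / (w_org + w_nuc) if (w_org + w_nuc) > 0 else 0.0
    beta = config.organelle_burst
    # seed-source probability adjusted so the marginal fragment source
    # fraction matches the copy-weighted mass fraction despite bursting
    denom = p_org + (1.0 - p_org) * (1.0 + beta)
    p_seed = p_org / denom if denom > 0 else 0.0
    mu_ln = math.log(config.frag_len_median)
    # mean reads per fragment so that one pool-sized batch of GEMs yields
    # roughly total_pairs
    frags_per_gem = config.frags_per_barcode_mean * (
        p_seed * (1.0 + beta) + (1.0 - p_seed))
    mean_pairs_per_frag = config.total_pairs / (config.barcode_pool * frags_per_gem)
    shape = config.reads_per_fragment_dispersion

    frags: list[_Fragment] = []
    for _ in range(n_gems):
        barcode = pool[int(rng.integers(0, len(pool)))]
        n_seeds = int(rng.poisson(config.frags_per_barcode_mean))
        for _ in range(n_seeds):
            if rng.random() < p_seed:
                n_frag = 1 + int(rng.poisson(beta))
                sources = ["organelle"] * n_frag
            else:
                sources = ["nuclear"]
            for src in sources:
                if src == "organelle":
                    src_len, circular, name = len(refs.organelle), True, "organelle"
                else:
                    idx = int(rng.integers(0, len(refs.nuclear))) if refs.nuclear else 0
                    src_len = len(refs.nuclear[idx])
                    circular, name = False, f"nuclear{idx}"
                flen = int(round(float(rng.lognormal(mu_ln, config.frag_len_sigma))))
                flen = max(1000, min(100_000, flen, src_len))
                if circular:
                    start = int(rng.integers(0, src_len))
                else:
                    start = int(rng.integers(0, src_len - flen + 1))
                lam = float(rng.gamma(shape, mean_pairs_per_frag / shape))
                n_pairs = int(rng.poisson(lam))
                frags.append(_Fragment(name, src_len, circular, start, flen,
                                       barcode, n_pairs))
    return frags


def simulate_linked_reads(refs: ReferenceSet, config: SimConfig
                          ) -> tuple[list[BarcodedReadPair], TruthTable]:
    """Emit exactly ``total_pairs`` barcoded read pairs plus ground truth.

    Fragments are drawn from the genomes with probability proportional to
    copy-ratio-weighted genome length; fragment lengths are log-normal with
    the configured median, truncated to [1 kb, 100 kb] and capped at the
    source length; organelle fragments may wrap the circular origin.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    pool = _barcode_pool(np.random.default_rng([config.seed, 2]),
                         config.barcode_pool)
    qual = _quality_string(config.read_length)
    rl = config.read_length

    sources = {"organelle": refs.organelle}
    for i, s in enumerate(refs.nuclear):
        sources[f"nuclear{i}"] = s

    pairs: list[BarcodedReadPair] = []
    truth = TruthTable()
    resampled_inserts = 0
    pair_idx = 0
    frag_idx = 0

    while len(pairs) < config.total_pairs:
        frags = _draw_fragments(refs, config, rng, pool, config.barcode_pool)
        for frag in frags:
            if len(pairs) >= config.total_pairs:
                break
            if frag.n_pairs == 0:
                frag_idx += 1
                continue
            src = sources[frag.source]
            if frag.circular:
                doubled = src + src[:frag.length]
                fseq = doubled[frag.start:frag.start + frag.length]
            else:
                fseq = src[frag.start:frag.start + frag.length]
            budget = min(frag.n_pairs, config.total_pairs - len(pairs))
            for _ in range(budget):
                insert = int(round(float(rng.normal(config.insert_mean,
                                                    config.insert_sd))))
                tries = 0
                while insert > frag.length or insert < rl:
                    resampled_inserts += 1
                    tries += 1
                    if tries > 50:
                        insert = min(frag.length, max(rl, insert))
                        break
                    insert = int(round(float(rng.normal(config.insert_mean,
                                                        config.insert_sd))))
                s = int(rng.integers(0, frag.length - insert + 1))
                fwd = fseq[s:s + rl]
                rev = revcomp(fseq[s + insert - rl:s + insert])
                start_fwd = (frag.start + s) % frag.src_len
                start_rev = (frag.start + s + insert - rl) % frag.src_len
                if rng.random() < 0.5:
                    seq1, seq2 = fwd, rev
                    start1, start2, strand = start_fwd, start_rev, "+"
                else:
                    seq1, seq2 = rev, fwd
                    start1, start2, strand = start_rev, start_fwd, "-"
                seq1 = _apply_errors(seq1, config.error_rate, rng)
                seq2 = _apply_errors(seq2, config.error_rate, rng)
                barcode = frag.barcode
                if config.n_barcode_rate > 0 and rng.random() < config.n_barcode_rate:
                    pos = int(rng.integers(0, len(barcode)))
                    barcode = barcode[:pos] + "N" + barcode[pos + 1:]
                name = f"sim{pair_idx}"
                pairs.append(BarcodedReadPair(name, seq1, qual, seq2, qual, barcode))
                truth.rows.append(TruthRow(name, frag.source, frag_idx, barcode,
                                           start1, start2, strand))
                pair_idx += 1
            frag_idx += 1

    return pairs, truth


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = int(rng.binomial(len(seq), rate))
    if n_err == 0:
        return seq
    out = list(seq)
    positions = rng.choice(len(seq), size=n_err, replace=False)
    for p in positions:
        old = out[p]
        choices = [b for b in BASES if b != old]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


def write_simulation(outdir, refs: ReferenceSet, config: SimConfig,
                     pairs: list[BarcodedReadPair], truth: TruthTable) -> dict:
    """Write FASTQ pair, truth TSV, references FASTA and config echo JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fastq1": outdir / "reads_1.fq",
        "fastq2": outdir / "reads_2.fq",
        "truth": outdir / "truth.tsv",
        "references": outdir / "references.fa",
        "config": outdir / "config.json",
    }
    write_paired_fastq(paths["fastq1"], paths["fastq2"], pairs)
    truth.to_tsv(paths["truth"])
    refs.write_fasta(paths["references"])
    config.to_json(paths["config"])
    return {k: str(v) for k, v in paths.items()}
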