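"""End-to-end orchestration: simulate -> bin -> assemble -> scaffold ->
fill -> circularize -> evaluate, behind one config-driven entry point.

All randomness flows from a single seed, fanned out to per-stage seeds by a
fixed derivation so every stage is independently reproducible.  The run
report records parameters, per-stage outputs and evaluation summaries and
round-trips losslessly as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from plastid_linker import barcode_binning, dbg_assembly, finishing, genome_eval
from plastid_linker import ref_scaffolding, synthetic_data
from plastid_linker.reads import (BarcodedReadPair, read_fasta,
                                  read_paired_fastq, write_fasta)
from plastid_linker.seq import canonical_kmer


class PipelineError(RuntimeError):
    """A stage failed; the report so far has been written."""


@dataclass
class RunConfig:
    """Everything one run needs; unknown keys in a config file are rejected."""

    seed: int = 0
    outdir: str = "run_out"
    # either simulate ...
    sim: dict = field(default_factory=dict)
    # ... or ingest external data
    fastq1: str | None = None
    fastq2: str | None = None
    reference: str | None = None
    # binning: pair-fraction targets, most to least inclusive
    bin_fractions: tuple[float, ...] = (0.40, 0.15, 0.05)
    bin_thresholds: tuple[int, ...] | None = None  # explicit override
    # assembly
    assembly_k: int = 48
    assembly_min_count: int | None = None  # None = sqrt-of-median auto cutoff
    assembly_min_len: int = 500
    trim_q: int = 15
    # scaffolding
    scaffold_k: int = 26
    scaffold_step: int = 1
    scaffold_min_support: int = 5
    scaffold_max_d: int = 16_000
    # gap filling
    sweep_hi: int = 125
    sweep_lo: int = 35
    limit_B: int = 3000
    limit_P: int = 20
    limit_F: int = 5000
    bloom_fpr: float = 0.001
    # circularization: descending k sweep (repeat phasing needs large k)
    circ_k_hi: int = 125
    circ_k_lo: int = 80
    circ_k_step: int = 5
    circ_max_fragment: int = 3500
    circ_end_len: int = 200

    def __post_init__(self):
        if self.bin_thresholds is not None:
            t = list(self.bin_thresholds)
            if t != sorted(set(t)):
                raise PipelineError("bin_thresholds must be strictly increasing")
        fr = list(self.bin_fractions)
        if fr != sorted(set(fr), reverse=True):
            raise PipelineError("bin_fractions must be strictly decreasing")

    def sim_config(self) -> synthetic_data.SimConfig:
        return synthetic_data.SimConfig(seed=self.seed, **self.sim)


def load_config(path) -> RunConfig:
    """Read a YAML config; defaults applied, unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    sim_known = {f.name for f in dataclasses.fields(synthetic_data.SimConfig)}
    sim_unknown = set(raw.get("sim", {})) - sim_known
    if sim_unknown:
        raise PipelineError(f"unknown sim key(s): {', '.join(sorted(sim_unknown))}")
    for key in ("bin_fractions", "bin_thresholds"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    d = asdict(config)
    for key in ("bin_fractions", "bin_thresholds"):
        if d[key] is not None:
            d[key] = list(d[key])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {canonical_kmer(seq[i:i + k]) for i in range(len(seq) - k + 1)
            if "N" not in seq[i:i + k]}


def pick_on_target_scaffold(scaffolds: list[tuple[str, str]], reference: str,
                            k: int = 26) -> tuple[str, str]:
    """The scaffold sharing the most canonical k-mers with the reference."""
    ref_kmers = _kmer_set(reference, k)
    best, best_hits = None, -1
    for name, seq in scaffolds:
        hits = len(_kmer_set(seq, k) & ref_kmers)
        if hits > best_hits:
            best, best_hits = (name, seq), hits
    if best is None or best_hits == 0:
        raise PipelineError("no scaffold maps to the reference")
    return best


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute all stages in order; returns the run report (also written
    to ``<outdir>/report.json`` along with stage FASTA artifacts)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": []}

    def stage(name: str, **info):
        report["stages"].append({"stage": name, **info})
        _write_report(report, outdir)

    try:
        # ---------------------------------------------------------- input
        truth_organelle = None
        ir_coords = None
        if config.fastq1:
            pairs = list(read_paired_fastq(config.fastq1, config.fastq2))
            reference = read_fasta(config.reference)[0][1]
            stage("ingest", pairs=len(pairs), reference_length=len(reference))
        else:
            sim = config.sim_config()
            refs = synthetic_data.generate_genomes(sim)
            truth_organelle = refs.organelle
            ir_coords = refs.ir_coords
            reference = synthetic_data.mutate_reference(
                refs.organelle, sim.related_divergence, sim.seed)
            pairs, truth = synthetic_data.simulate_linked_reads(refs, sim)
            truth.to_tsv(outdir / "truth.tsv")
            write_fasta(outdir / "references.fa",
                        [("organelle", refs.organelle),
                         ("related_reference", reference)])
            stage("simulate", pairs=len(pairs),
                  organelle_length=len(refs.organelle),
                  ir_coords=list(map(list, ir_coords)) if ir_coords else None,
                  related_reference_length=len(reference))

        # --------------------------------------------------------- binning
        table = barcode_binning.count_index_multiplicity(pairs)
        if config.bin_thresholds is not None:
            thresholds = list(config.bin_thresholds)
        else:
            thresholds = [table.threshold_for_fraction(f)
                          for f in config.bin_fractions]
        bins = [barcode_binning.bin_reads(pairs, table, t) for t in thresholds]
        stage("binning", thresholds=thresholds,
              bin_pairs=[len(b.pairs) for b in bins],
              bin_fractions=[round(b.fraction_of_total, 4) for b in bins],
              excluded_ambiguous=table.excluded_ambiguous)

        # -------------------------------------------------------- assembly
        top_bin = bins[-1] if bins else None
        assembly_pairs = top_bin.pairs if top_bin else pairs
        degenerate = top_bin is None
        trimmed = dbg_assembly.trim_reads(assembly_pairs, q=config.trim_q,
                                          min_len=config.assembly_k)
        graph = dbg_assembly.build_graph(trimmed.sequences, config.assembly_k,
                                         min_count=1)
        min_count = (config.assembly_min_count
                     or dbg_assembly.auto_min_count(graph.counts))
        graph.counts = {km: c for km, c in graph.counts.items()
                        if c >= min_count}
        blunt = dbg_assembly.blunt_end_fraction(graph)
        contigs = dbg_assembly.build_unitigs(graph, config.assembly_min_len)
        write_fasta(outdir / "contigs.fa",
                    [(c.id, c.sequence) for c in contigs])
        stage("assembly", degenerate_all_reads=degenerate,
              reads_after_trim=len(trimmed.sequences), dropped=trimmed.dropped,
              k=config.assembly_k, min_count=min_count,
              graph_vertices=len(graph.counts),
              blunt_end_fraction=round(blunt, 4), contigs=len(contigs))
        if not contigs:
            raise PipelineError("assembly produced no contigs")

        # ------------------------------------------------------ scaffolding
        schedule = ref_scaffolding.default_distance_schedule(config.scaffold_max_d)
        schedule = [d for d in schedule
                    if d + config.scaffold_k < len(reference)]
        scaffolds = ref_scaffolding.iterate_distances(
            [(c.id, c.sequence) for c in contigs], reference, schedule,
            k=config.scaffold_k, step=config.scaffold_step,
            min_support=config.scaffold_min_support)
        write_fasta(outdir / "scaffolds.fa", scaffolds)
        name, scaffold = pick_on_target_scaffold(scaffolds, reference,
                                                 config.scaffold_k)
        n_gaps = len(finishing.find_gaps(scaffold))
        stage("scaffolding", scaffolds=len(scaffolds), on_target=name,
              scaffold_length=len(scaffold), gaps=n_gaps)

        # ------------------------------------------------------ gap filling
        sweep = finishing.default_k_sweep(config.sweep_hi, config.sweep_lo)
        limits = finishing.PathSearchLimits(config.limit_B, config.limit_P,
                                            config.limit_F)
        fill_bins = [b.pairs for b in reversed(bins[:-1])] + [list(pairs)]
        if not fill_bins:
            fill_bins = [list(pairs)]
        scaffold, rounds = finishing.fill_all_gaps(
            scaffold, fill_bins, reference, sweep, limits,
            fpr=config.bloom_fpr)
        round_stats = [
            {"round": i + 1,
             "attempted": len(r),
             "closed": sum(1 for x in r if x.status == "closed"),
             "statuses": {f"{x.gap.start}-{x.gap.end}": x.status for x in r}}
            for i, r in enumerate(rounds)]
        remaining = len(finishing.find_gaps(scaffold))
        write_fasta(outdir / "filled.fa", [("filled_scaffold", scaffold)])
        stage("gap_filling", rounds=round_stats, remaining_gaps=remaining)

        # --------------------------------------------------- circularization
        circular = False
        if remaining == 0:
            circ_reads = [s for p in fill_bins[0] for s in (p.seq1, p.seq2)]
            circ_sweep = list(range(config.circ_k_hi, config.circ_k_lo - 1,
                                    -config.circ_k_step))
            try:
                scaffold = finishing.join_ends(
                    scaffold, circ_reads, k=circ_sweep,
                    max_fragment=config.circ_max_fragment,
                    end_len=config.circ_end_len, limits=limits,
                    fpr=config.bloom_fpr)
                circular = True
            except finishing.NotCircularizable as exc:
                stage("circularize", circular=False, reason=str(exc))
        if circular:
            scaffold = finishing.canonical_rotation(scaffold, reference)
            stage("circularize", circular=True, length=len(scaffold))
        write_fasta(outdir / "final.fa", [("final", scaffold)])

        # -------------------------------------------------------- evaluation
        comp = genome_eval.composition(scaffold)
        amb = genome_eval.ambiguity_stats(scaffold)
        evaluation: dict[str, Any] = {
            "length": len(scaffold),
            "gc_percent": round(comp.gc_percent, 1),
            "composition": {b: round(v, 1) for b, v in
                            (("A", comp.percent_a), ("C", comp.percent_c),
                             ("G", comp.percent_g), ("T", comp.percent_t))},
            "ambiguous_bases": amb.ambiguous,
            "n_runs": amb.n_runs,
            "circular": circular,
        }
        try:
            ir = genome_eval.detect_inverted_repeat(scaffold)
            evaluation["inverted_repeat"] = {
                "found": ir.found, "length": ir.length,
                "substitutions": ir.substitutions,
                "copy1": list(ir.copy1) if ir.copy1 else None,
                "copy2": list(ir.copy2) if ir.copy2 else None,
            }
        except ValueError:
            evaluation["inverted_repeat"] = {"found": False}
        if truth_organelle is not None:
            cmp_res = genome_eval.compare_to_truth(scaffold, truth_organelle,
                                                   circular=circular)
            evaluation["truth_comparison"] = {
                "exact_match": cmp_res.exact_match,
                "length_difference": cmp_res.length_difference,
                "mismatches": cmp_res.mismatches,
                "orientation": cmp_res.orientation,
            }
        stage("evaluate", **evaluation)
        report["final"] = evaluation
    except PipelineError:
        _write_report(report, outdir)
        raise
    _write_report(report, outdir)
    return report


def _write_report(report: dict, outdir: Path) -> None:
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
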