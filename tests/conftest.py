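"""Shared fixtures: a small seeded simulation reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from plastid_linker.barcode_binning import count_index_multiplicity
from plastid_linker.synthetic_data import (SimConfig, generate_genomes,
                                           mutate_reference,
                                           simulate_linked_reads)


SMALL_SIM_KW = dict(seed=7, total_pairs=12_000, nuclear_length=100_000)


@pytest.fixture(scope="session")
def small_sim():
    """A small linked-read simulation: (config, refs, pairs, truth)."""
    cfg = SimConfig(**SMALL_SIM_KW)
    refs = generate_genomes(cfg)
    pairs, truth = simulate_linked_reads(refs, cfg)
    return cfg, refs, pairs, truth


@pytest.fixture(scope="session")
def small_table(small_sim):
    _, _, pairs, _ = small_sim
    return count_index_multiplicity(pairs)


@pytest.fixture(scope="session")
def related_reference(small_sim):
    cfg, refs, _, _ = small_sim
    return mutate_reference(refs.organelle, cfg.related_divergence, cfg.seed)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


@pytest.fixture()
def make_dna(rng):
    def _make(n: int) -> str:
        return random_dna(rng, n)
    return _make
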