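"""Shared fixtures: deterministic hypothesis profile and simulated trios.

The two session-scoped trios are the package's reference study conditions:
a mutation-free trio for exact sector recovery and a diverged trio
(substitutions + small indels, 60x error-free reads) for coverage-based
region calling.  Both use a 1 Mbp core in 20 segments, ten 0.5-5 kbp
specific segments per genome, a few pairwise-shared segments, and one
50-copy repeat family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pantrio.align import AlignerConfig, ReferenceIndex, align_genomes
from pantrio.kmers import KmerDB, count_kmers, profile_sequence_set
from pantrio.pangenome import SectorLabeling, classify_bases
from pantrio.simulate import SimConfig, simulate_reads, simulate_trio

settings.register_profile(
    "pantrio", deadline=None, derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large])
settings.load_profile("pantrio")


def trio_config(seed: int, snp_rate: float, *, core_length: int = 1_000_000,
                n_specific: int = 10, repeat_in_specific: int = 0,
                depth: float = 60.0) -> SimConfig:
    """The reference trio study condition at a given divergence."""
    rng = np.random.default_rng(seed + 10_000)
    spec = {s: [int(x) for x in rng.integers(500, 5001, size=n_specific)]
            for s in ("A", "B", "C")}
    return SimConfig(
        seed=seed, core_length=core_length, core_segments=20,
        sector_segment_lengths={**spec, "AB": [2000, 1500], "AC": [1800],
                                "BC": [2500]},
        snp_rate=snp_rate, small_indel_rate=snp_rate / 10,
        repeat_family_specs=[(400, 50)], repeat_in_specific=repeat_in_specific,
        gene_density=1.0, read_depth=depth, read_length=100,
        read_error_rate=0.0)


@dataclass
class TrioRun:
    config: SimConfig
    genomes: dict
    annotations: dict
    truth: object
    labelings: dict[str, SectorLabeling] = field(default_factory=dict)
    dbs: dict[str, KmerDB] = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)   # profiles[focal][db_genome]


def run_trio(config: SimConfig, with_reads: bool) -> TrioRun:
    genomes, annotations, truth = simulate_trio(config)
    run = TrioRun(config, genomes, annotations, truth)
    acfg = AlignerConfig()
    order = list(genomes)
    for g in order:
        others = tuple(h for h in order if h != g)
        index = ReferenceIndex(genomes[g], acfg)
        uns = [align_genomes(genomes[g], genomes[h], acfg, index=index)
               .unaligned(genomes[g]) for h in others]
        run.labelings[g] = classify_bases(genomes[g].lengths(), uns[0], uns[1],
                                          g, others)
    if with_reads:
        for i, g in enumerate(order):
            reads = simulate_reads(genomes[g], config, seed=config.seed * 10 + i)
            run.dbs[g] = count_kmers((seq for _name, seq in reads), k=21)
        for g in order:
            run.profiles[g] = {h: profile_sequence_set(genomes[g], run.dbs[h])
                               for h in order}
    return run


@pytest.fixture(scope="session")
def exact_trio() -> TrioRun:
    """Mutation-free trio at full scale; alignments only (no reads needed)."""
    return run_trio(trio_config(seed=11, snp_rate=0.0), with_reads=False)


@pytest.fixture(scope="session")
def divergent_trio() -> TrioRun:
    """Diverged trio (snp 0.005) with 60x error-free reads and k-mer profiles."""
    return run_trio(trio_config(seed=11, snp_rate=0.005), with_reads=True)


@pytest.fixture(scope="session")
def repeat_trio() -> TrioRun:
    """Smaller diverged trio with repeat copies scattered into specific segments."""
    cfg = trio_config(seed=7, snp_rate=0.005, core_length=200_000,
                      n_specific=4, repeat_in_specific=2)
    return run_trio(cfg, with_reads=True)
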