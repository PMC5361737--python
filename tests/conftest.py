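from __future__ import annotations

import numpy as np
import pytest

from chiprx.assign import (
    AlignmentRecord,
    assign_reads,
    index_concatenated_genome,
    merged_chrom_name,
)
from chiprx.simdata import (
    ReferenceGenome,
    SampleLibrary,
    SimulationConfig,
    build_toy_genomes,
    simulate_chiprx_experiment,
)


def truth_alignments(library: SampleLibrary) -> list[AlignmentRecord]:
    """Alignments reconstructed from simulation truth tags (bypasses assign)."""
    out = []
    for read in library.reads:
        out.append(
            AlignmentRecord(
                read_id=read.id,
                genome_label=read.truth_genome,
                chrom=merged_chrom_name(read.truth_genome, read.truth_chrom),
                start=read.truth_position,
                end=read.truth_position + len(read.sequence),
                strand=read.truth_strand,
            )
        )
    return out


def truth_counts(library: SampleLibrary):
    from chiprx.assign import CountSummary

    n_spike = sum(1 for r in library.reads if r.truth_genome == "spikein")
    return CountSummary(len(library.reads) - n_spike, n_spike, 0, 0)


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11, depth=20_000)


@pytest.fixture(scope="session")
def experiment(default_config):
    """Full small experiment: genomes, libraries, index, assignments, counts."""
    target, spikein = build_toy_genomes(default_config)
    libraries = simulate_chiprx_experiment(default_config, (target, spikein))
    index = index_concatenated_genome(target, spikein, default_config.read_length)
    aligned = {}
    counts = {}
    for lib in libraries:
        alignments, summary = assign_reads(lib.reads, index)
        aligned[lib.sample_id] = alignments
        counts[lib.sample_id] = summary
    return {
        "config": default_config,
        "target": target,
        "spikein": spikein,
        "libraries": {lib.sample_id: lib for lib in libraries},
        "index": index,
        "chrom_sizes": dict(index.chrom_sizes),
        "aligned": aligned,
        "counts": counts,
    }


@pytest.fixture()
def tiny_genomes() -> tuple[ReferenceGenome, ReferenceGenome]:
    """Deterministic random genomes <= 5 kb for oracle tests."""
    rng = np.random.default_rng(1234)
    bases = np.frombuffer(b"ACGT", dtype="S1")

    def seq(n):
        return rng.choice(bases, size=n).tobytes().decode()

    target = ReferenceGenome("target", {"chrA": seq(3000), "chrB": seq(1500)})
    spikein = ReferenceGenome("spikein", {"chrS": seq(1000)})
    return target, spikein
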