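"""Synthetic ChIP-Rx experiment generator.

Generates toy target and spike-in genomes with marked loci and simulates
pulldown/input sequencing libraries for a treated and a vehicle condition.
The generative model mirrors the assumptions of spike-in quantification:

* each sample is a chromatin pool mixing target and spike-in cells; the
  genome-of-origin proportion of a fragment follows cell number weighted by
  genome length;
* input libraries sample fragments uniformly from the pool;
* pulldown libraries capture a fragment overlapping a marked locus with
  probability ``pulldown_efficiency * occupancy`` (occupancy multiplied by
  ``fold_change`` on target loci in the treated condition only) and any other
  fragment with probability ``background_capture``;
* spike-in chromatin and its occupancy are identical across conditions.

All randomness flows from the mandatory config seed, so identical configs
produce byte-identical libraries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Iterator, Literal, Optional

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype="S1")

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.encode("ascii").translate(_COMPLEMENT)[::-1].decode("ascii")


@dataclass(frozen=True)
class MarkedLocus:
    """Ground-truth marked interval (0-based half-open)."""

    chrom: str
    start: int
    end: int


@dataclass
class ReferenceGenome:
    """A named set of chromosome sequences labeled target or spike-in.

    ``marked_loci`` records the ground-truth marked intervals placed by the
    generator (empty for externally loaded genomes).
    """

    label: Literal["target", "spikein"]
    chromosomes: dict[str, str]
    marked_loci: list[MarkedLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("target", "spikein"):
            raise ValueError(f"invalid genome label: {self.label!r}")
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name!r} contains non-ACGT characters")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def chrom_sizes(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic ChIP-Rx experiment.

    Defaults follow the emulated wet-lab design: 1e7 target cells mixed with
    3e6 spike-in cells, 83 bp reads, a treated condition whose target-locus
    occupancy is uniformly multiplied by ``fold_change`` while spike-in
    chromatin is untouched.
    """

    seed: int
    n_target_cells: int = 10_000_000
    n_spikein_cells: int = 3_000_000
    read_length: int = 83
    paired: bool = False
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 50.0
    target_genome_bp: int = 200_000
    spikein_genome_bp: int = 60_000
    n_marked_loci_target: int = 50
    n_marked_loci_spikein: int = 15
    locus_width: int = 1_000
    base_occupancy: float = 0.5
    fold_change: float = 2.0
    pulldown_efficiency: float = 0.9
    background_capture: float = 0.02
    depth: int = 50_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "n_target_cells",
            "n_spikein_cells",
            "n_marked_loci_target",
            "n_marked_loci_spikein",
            "depth",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.locus_width <= 0:
            raise ValueError("locus_width must be positive")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        for name in ("base_occupancy", "pulldown_efficiency", "background_capture"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fragment_length_mean < self.read_length:
            raise ValueError("fragment_length_mean must be >= read_length")
        if self.fragment_length_sd < 0:
            raise ValueError("fragment_length_sd must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(slots=True)
class ReadRecord:
    """A simulated read with its provenance tags.

    ``truth_*`` fields identify the fragment of origin in the simulated
    coordinate space (the forward-strand interval covered by the read) and
    are present only on simulated reads.
    """

    id: str
    sequence: str
    mate: Optional[str] = None
    truth_genome: Optional[str] = None
    truth_chrom: Optional[str] = None
    truth_position: Optional[int] = None
    truth_strand: Optional[str] = None


@dataclass
class SampleLibrary:
    """One sequencing library: pulldown or input, treated or vehicle."""

    sample_id: str
    role: Literal["pulldown", "input"]
    condition: Literal["treated", "vehicle"]
    reads: list[ReadRecord]

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[ReadRecord]:
        return iter(self.reads)


def _place_loci(
    rng: np.random.Generator, chrom_len: int, n_loci: int, width: int
) -> list[tuple[int, int]]:
    """Place n non-overlapping loci of fixed width uniformly on a chromosome."""
    if n_loci == 0:
        return []
    # slot model: choose starts so that loci are disjoint
    slack = chrom_len - n_loci * width
    if slack < 0 or chrom_len < 10 * width:
        raise ValueError(
            f"genome of {chrom_len} bp too small for {n_loci} loci of {width} bp"
        )
    gaps = rng.multinomial(slack, np.full(n_loci + 1, 1.0 / (n_loci + 1)))
    starts = []
    pos = 0
    for i in range(n_loci):
        pos += gaps[i]
        starts.append(pos)
        pos += width
    return [(s, s + width) for s in starts]


def build_toy_genomes(
    config: SimulationConfig,
) -> tuple[ReferenceGenome, ReferenceGenome]:
    """Generate independent random target and spike-in genomes.

    Each genome is a single chromosome (``chr1``) of i.i.d. uniform bases, so
    exact cross-genome matches of ``read_length`` are vanishingly rare.
    Marked-locus coordinates are recorded on each genome as ground truth.
    """
    rng = np.random.default_rng(config.seed)
    genomes = []
    for label, size, n_loci in (
        ("target", config.target_genome_bp, config.n_marked_loci_target),
        ("spikein", config.spikein_genome_bp, config.n_marked_loci_spikein),
    ):
        seq = rng.choice(BASES, size=size).tobytes().decode("ascii")
        loci = [
            MarkedLocus("chr1", s, e)
            for s, e in _place_loci(rng, size, n_loci, config.locus_width)
        ]
        genomes.append(ReferenceGenome(label=label, chromosomes={"chr1": seq}, marked_loci=loci))
    return genomes[0], genomes[1]


def _locus_mask(genome: ReferenceGenome) -> dict[str, np.ndarray]:
    masks = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.chromosomes.items()}
    for locus in genome.marked_loci:
        masks[locus.chrom][locus.start : locus.end] = True
    return masks


class _GenomeSampler:
    """Vectorized fragment sampler over one genome."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        self.chrom_names = list(genome.chromosomes)
        self.chrom_lens = np.array([len(genome.chromosomes[c]) for c in self.chrom_names])
        self.chrom_probs = self.chrom_lens / self.chrom_lens.sum()
        self.locus_masks = _locus_mask(genome)

    def draw_fragments(
        self, rng: np.random.Generator, n: int, config: SimulationConfig
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Draw n fragments: (chrom_idx, start, length, overlaps_marked_locus)."""
        chrom_idx = rng.choice(len(self.chrom_names), size=n, p=self.chrom_probs)
        lengths = rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n)
        lengths = np.maximum(np.rint(lengths), config.read_length).astype(np.int64)
        max_start = self.chrom_lens[chrom_idx] - lengths
        # fragments must fit; clip lengths on short chromosomes
        short = max_start < 0
        if short.any():
            lengths[short] = self.chrom_lens[chrom_idx[short]]
            max_start[short] = 0
        starts = (rng.random(n) * (max_start + 1)).astype(np.int64)
        marked = np.zeros(n, dtype=bool)
        for ci, name in enumerate(self.chrom_names):
            sel = chrom_idx == ci
            if not sel.any():
                continue
            mask = self.locus_masks[name]
            cum = np.concatenate(([0], np.cumsum(mask)))
            s, e = starts[sel], starts[sel] + lengths[sel]
            marked[sel] = (cum[e] - cum[s]) > 0
        return chrom_idx, starts, lengths, marked


def _capture_probability(
    marked: np.ndarray,
    is_spikein: bool,
    role: str,
    condition: str,
    config: SimulationConfig,
) -> np.ndarray:
    if role == "input":
        return np.ones(marked.shape)
    occ = config.base_occupancy
    if not is_spikein and condition == "treated":
        occ = occ * config.fold_change
    p_marked = min(1.0, config.pulldown_efficiency * occ)
    return np.where(marked, p_marked, config.background_capture)


def _extract_reads(
    genome: ReferenceGenome,
    sampler: _GenomeSampler,
    chrom_idx: np.ndarray,
    starts: np.ndarray,
    lengths: np.ndarray,
    strands: np.ndarray,
    config: SimulationConfig,
    id_prefix: str,
    id_offset: int,
) -> list[ReadRecord]:
    reads = []
    L = config.read_length
    for i in range(len(starts)):
        chrom = sampler.chrom_names[chrom_idx[i]]
        seq = genome.chromosomes[chrom]
        s, flen = int(starts[i]), int(lengths[i])
        if strands[i]:  # minus strand: read from the 3' end of the fragment
            read_start = s + flen - L
            read_seq = reverse_complement(seq[read_start : read_start + L])
            strand = "-"
        else:
            read_start = s
            read_seq = seq[s : s + L]
            strand = "+"
        mate = None
        if config.paired:
            if strand == "+":
                mate = reverse_complement(seq[s + flen - L : s + flen])
            else:
                mate = seq[s : s + L]
        rid = f"{id_prefix}:{id_offset + i:07d}"
        reads.append(
            ReadRecord(
                id=rid,
                sequence=read_seq,
                mate=mate,
                truth_genome=genome.label,
                truth_chrom=chrom,
                truth_position=read_start,
                truth_strand=strand,
            )
        )
    return reads


def _simulate_library(
    rng: np.random.Generator,
    role: str,
    condition: str,
    target_sampler: _GenomeSampler,
    spikein_sampler: _GenomeSampler,
    config: SimulationConfig,
    spikein_cell_scale: float = 1.0,
) -> SampleLibrary:
    sample_id = f"{condition}_{role}"
    if config.depth == 0:
        warnings.warn(f"{sample_id}: depth=0, emitting empty library", stacklevel=2)
        return SampleLibrary(sample_id, role, condition, [])

    w_target = config.n_target_cells * target_sampler.chrom_lens.sum()
    w_spike = config.n_spikein_cells * spikein_cell_scale * spikein_sampler.chrom_lens.sum()
    total = w_target + w_spike
    if total == 0:
        raise ValueError("chromatin pool is empty: zero cells for both genomes")
    p_spike = w_spike / total

    reads: list[ReadRecord] = []
    # rejection-sample in batches until the library reaches target depth;
    # accepted reads keep their within-batch draw order so truncation to
    # `depth` does not bias library composition
    batch = max(2 * config.depth, 10_000)
    while len(reads) < config.depth:
        origin_spike = rng.random(batch) < p_spike
        batch_reads: list[tuple[int, ReadRecord]] = []
        for is_spike, sampler in ((False, target_sampler), (True, spikein_sampler)):
            pos = np.flatnonzero(origin_spike == is_spike)
            n = pos.size
            if n == 0:
                continue
            chrom_idx, starts, lengths, marked = sampler.draw_fragments(rng, n, config)
            p_cap = _capture_probability(marked, is_spike, role, condition, config)
            keep = rng.random(n) < p_cap
            strands = rng.random(n) < 0.5
            kept = np.flatnonzero(keep)
            if kept.size == 0:
                continue
            new = _extract_reads(
                sampler.genome,
                sampler,
                chrom_idx[kept],
                starts[kept],
                lengths[kept],
                strands[kept],
                config,
                sample_id,
                0,
            )
            batch_reads.extend(zip(pos[kept].tolist(), new))
        batch_reads.sort(key=lambda t: t[0])
        reads.extend(r for _, r in batch_reads)
    reads = reads[: config.depth]
    # number ids contiguously in draw order
    for i, r in enumerate(reads):
        r.id = f"{sample_id}:{i:07d}"
    return SampleLibrary(sample_id, role, condition, reads)


def simulate_chiprx_experiment(
    config: SimulationConfig,
    genomes: tuple[ReferenceGenome, ReferenceGenome],
    spikein_cell_scale: dict[str, float] | None = None,
) -> list[SampleLibrary]:
    """Simulate the four libraries of a ChIP-Rx experiment.

    Returns ``[treated_pulldown, treated_input, vehicle_pulldown,
    vehicle_input]``. ``spikein_cell_scale`` optionally multiplies the
    spike-in cell number per condition (pipetting-variability experiments);
    the same multiplier applies to a condition's pulldown and its input.
    """
    target, spikein = genomes
    if target.label != "target" or spikein.label != "spikein":
        raise ValueError("genomes must be passed as (target, spikein)")
    spikein_cell_scale = spikein_cell_scale or {}
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    target_sampler = _GenomeSampler(target)
    spikein_sampler = _GenomeSampler(spikein)
    libraries = []
    for condition in ("treated", "vehicle"):
        k = spikein_cell_scale.get(condition, 1.0)
        for role in ("pulldown", "input"):
            libraries.append(
                _simulate_library(
                    rng, role, condition, target_sampler, spikein_sampler, config, k
                )
            )
    return libraries
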