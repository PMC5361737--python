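"""Unique exact-match read assignment to a concatenated two-genome index.

Emulates alignment to a merged target/spike-in genome keeping only reads
that match uniquely to one location over both strands of both genomes.
Chromosomes live in a merged namespace prefixed ``target|`` / ``spikein|``
so every alignment carries unambiguous genome attribution.

Matching is exact (0 mismatches): synthetic reads carry no sequencing
error, so exact unique matching preserves the unique-mapping semantics of
the real aligner without external dependencies. Externally produced BED6
alignments can be imported instead (see :func:`load_alignments_bed`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from chiprx.simdata import ReadRecord, ReferenceGenome, reverse_complement

TARGET_PREFIX = "target|"
SPIKEIN_PREFIX = "spikein|"


def merged_chrom_name(label: str, chrom: str) -> str:
    return f"{label}|{chrom}"


def genome_of_chrom(chrom: str) -> str:
    """Infer genome label from a merged chromosome name."""
    if chrom.startswith(TARGET_PREFIX):
        return "target"
    if chrom.startswith(SPIKEIN_PREFIX):
        return "spikein"
    raise ValueError(f"chromosome {chrom!r} lacks a target|/spikein| prefix")


@dataclass(slots=True, frozen=True)
class AlignmentRecord:
    """A unique placement of one read in merged coordinates (0-based half-open)."""

    read_id: str
    genome_label: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class CountSummary:
    """Partition of a library's reads by assignment outcome."""

    n_target: int
    n_spikein: int
    n_discarded_multi: int
    n_unmapped: int

    def __post_init__(self) -> None:
        for f in ("n_target", "n_spikein", "n_discarded_multi", "n_unmapped"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def n_aligned(self) -> int:
        return self.n_target + self.n_spikein

    @property
    def total(self) -> int:
        return self.n_target + self.n_spikein + self.n_discarded_multi + self.n_unmapped


class GenomeIndex:
    """Exact-match k-mer index over the forward strands of a merged genome.

    A query of length k is looked up as-is (``+`` hits) and as its reverse
    complement (``-`` hits); together this covers both strands. For odd k a
    read can never equal its own reverse complement, so the two lookups
    cannot double-count a location.
    """

    def __init__(self, k: int, chrom_seqs: dict[str, str]):
        self.k = k
        self.chrom_seqs = chrom_seqs
        self.chrom_sizes = {c: len(s) for c, s in chrom_seqs.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in chrom_seqs.items():
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                self._index.setdefault(kmer, []).append((chrom, pos))

    def occurrences(self, query: str) -> list[tuple[str, int, str]]:
        """All (chrom, start, strand) placements of `query` on either strand."""
        if len(query) != self.k:
            raise ValueError(f"query length {len(query)} != index k {self.k}")
        hits = [(c, p, "+") for c, p in self._index.get(query, ())]
        rc = reverse_complement(query)
        hits += [(c, p, "-") for c, p in self._index.get(rc, ())]
        return hits


def index_concatenated_genome(
    target: ReferenceGenome, spikein: ReferenceGenome, read_length: int
) -> GenomeIndex:
    """Build the merged exact-match index over both genomes.

    Chromosome names are prefixed with their genome label; a duplicate name
    after prefixing is an error.
    """
    if target.label != "target" or spikein.label != "spikein":
        raise ValueError("expected genomes labeled 'target' and 'spikein'")
    merged: dict[str, str] = {}
    for genome in (target, spikein):
        for chrom, seq in genome.chromosomes.items():
            name = merged_chrom_name(genome.label, chrom)
            if name in merged:
                raise ValueError(f"duplicate merged chromosome name {name!r}")
            merged[name] = seq
    return GenomeIndex(read_length, merged)


def assign_reads(
    reads: Iterable[ReadRecord], index: GenomeIndex
) -> tuple[list[AlignmentRecord], CountSummary]:
    """Assign each read to its unique location, or discard it.

    One exact occurrence over both strands of both genomes yields an
    AlignmentRecord; zero occurrences count as unmapped; two or more as
    multi-mapping discards. The returned CountSummary partitions the input
    exactly.
    """
    alignments: list[AlignmentRecord] = []
    n_target = n_spikein = n_multi = n_unmapped = 0
    k = index.k
    for read in reads:
        if len(read.sequence) != k:
            raise ValueError(
                f"read {read.id!r} has length {len(read.sequence)}, index expects {k}"
            )
        hits = index.occurrences(read.sequence)
        if len(hits) == 0:
            n_unmapped += 1
        elif len(hits) > 1:
            n_multi += 1
        else:
            chrom, start, strand = hits[0]
            label = genome_of_chrom(chrom)
            alignments.append(
                AlignmentRecord(
                    read_id=read.id,
                    genome_label=label,
                    chrom=chrom,
                    start=start,
                    end=start + k,
                    strand=strand,
                )
            )
            if label == "target":
                n_target += 1
            else:
                n_spikein += 1
    summary = CountSummary(n_target, n_spikein, n_multi, n_unmapped)
    n_in = len(reads) if isinstance(reads, Sequence) else summary.total
    assert summary.total == n_in, "count summary must partition the input"
    return alignments, summary


def summarize_alignments(alignments: Iterable[AlignmentRecord]) -> CountSummary:
    """CountSummary for pre-assigned alignments (no unmapped/multi information)."""
    n_target = n_spikein = 0
    for a in alignments:
        if a.genome_label == "target":
            n_target += 1
        else:
            n_spikein += 1
    return CountSummary(n_target, n_spikein, 0, 0)
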