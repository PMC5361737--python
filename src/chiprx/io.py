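"""Text-format readers and writers: FASTA, FASTQ, BED6, bedGraph, TSV tables.

All genomic coordinates on disk follow the BED/bedGraph convention:
0-based, half-open.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from chiprx.assign import AlignmentRecord, CountSummary, genome_of_chrom
from chiprx.peaks import Peak
from chiprx.simdata import MarkedLocus, ReadRecord, ReferenceGenome, SampleLibrary
from chiprx.spikenorm import ScalingResult
from chiprx.tracks import CoverageTrack


# --- FASTA ------------------------------------------------------------------

def write_fasta(genome: ReferenceGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, label: str) -> ReferenceGenome:
    chromosomes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return ReferenceGenome(label=label, chromosomes=chromosomes)


# --- FASTQ ------------------------------------------------------------------

def write_fastq(library: SampleLibrary, path: str | Path) -> None:
    """Write reads with a constant placeholder quality (no error model)."""
    with open(path, "w") as fh:
        for read in library.reads:
            fh.write(f"@{read.id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(ReadRecord(id=rec.id, sequence=str(rec.seq).upper()))
    return reads


# --- BED --------------------------------------------------------------------

def write_alignments_bed(alignments: Iterable[AlignmentRecord], path: str | Path) -> None:
    """BED6: chrom, start, end, name=read_id, score=0, strand."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.read_id}\t0\t{a.strand}\n")


def read_alignments_bed(path: str | Path) -> list[AlignmentRecord]:
    """Import BED6 alignments; genome inferred from the chromosome-name prefix."""
    alignments = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            alignments.append(
                AlignmentRecord(
                    read_id=name,
                    genome_label=genome_of_chrom(chrom),
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    return alignments


def write_loci_bed(loci: Iterable[MarkedLocus], path: str | Path, prefix: str = "") -> None:
    with open(path, "w") as fh:
        for i, locus in enumerate(loci):
            chrom = f"{prefix}{locus.chrom}" if prefix else locus.chrom
            fh.write(f"{chrom}\t{locus.start}\t{locus.end}\tlocus_{i:04d}\t0\t.\n")


def read_tss_bed(path: str | Path) -> list[tuple[str, int, str]]:
    """TSS sites from BED6 (uses start as the site position) or 3-column TSV."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 6:
                sites.append((parts[0], int(parts[1]), parts[5]))
            else:
                sites.append((parts[0], int(parts[1]), parts[2] if len(parts) > 2 else "+"))
    return sites


# --- bedGraph ---------------------------------------------------------------

def write_bedgraph(track: CoverageTrack, path: str | Path, header: bool = False) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(
                f'track type=bedGraph name="{track.sample_id}" '
                f"description=\"{track.normalization} strand={track.strand}\"\n"
            )
        for chrom, start, end, value in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


def read_bedgraph(
    path: str | Path,
    chrom_sizes: dict[str, int],
    sample_id: str = "",
    strand: str = "both",
    normalization: str = "raw",
) -> CoverageTrack:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.rstrip("\n").split("\t")[:4]
            intervals.append((chrom, int(start), int(end), float(value)))
    return CoverageTrack(
        sample_id=sample_id,
        strand=strand,
        normalization=normalization,
        intervals=intervals,
        chrom_sizes=dict(chrom_sizes),
    )


# --- TSV tables -------------------------------------------------------------

COUNT_FIELDS = ("n_target", "n_spikein", "n_discarded_multi", "n_unmapped")


def write_counts_tsv(counts: CountSummary, path: str | Path, sample_id: str = "") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("sample_id",) + COUNT_FIELDS)
        writer.writerow([sample_id] + [getattr(counts, f) for f in COUNT_FIELDS])


def read_counts_tsv(path: str | Path) -> tuple[str, CountSummary]:
    with open(path) as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    if len(rows) != 1:
        raise ValueError(f"expected one row in {path}, found {len(rows)}")
    row = rows[0]
    return row.get("sample_id", ""), CountSummary(*(int(row[f]) for f in COUNT_FIELDS))


SCALING_FIELDS = (
    "sample_id",
    "sf9_rpm_pulldown",
    "input_sf9_fraction",
    "corrected_sf9_rpm",
    "scale_factor",
    "rpm_factor",
)


def write_scaling_tsv(results: Sequence[ScalingResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(SCALING_FIELDS)
        for r in results:
            writer.writerow(
                [r.sample_id] + [f"{getattr(r, f):.12g}" for f in SCALING_FIELDS[1:]]
            )


def read_scaling_tsv(path: str | Path) -> list[ScalingResult]:
    with open(path) as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return [
        ScalingResult(
            sample_id=row["sample_id"],
            **{f: float(row[f]) for f in SCALING_FIELDS[1:]},
        )
        for row in rows
    ]


def write_manifest_tsv(
    entries: Sequence[dict], path: str | Path
) -> None:
    """Library manifest: sample_id, role, condition, and file paths."""
    fields = ["sample_id", "role", "condition", "fastq", "bed", "counts"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, delimiter="\t", lineterminator="\n")
        writer.writeheader()
        for entry in entries:
            writer.writerow({k: entry.get(k, "") for k in fields})


def read_manifest_tsv(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def write_peaks_broadpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    """broadPeak-like BED6+: name, score, strand '.', fold_enrichment, -log10 p."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = min(1000, int(round(10 * p.score)))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i:04d}\t{score}\t.\t"
                f"{p.fold_enrichment:.6g}\t{p.score:.6g}\n"
            )


def read_peaks_broadpeak(path: str | Path) -> list[Peak]:
    """Import broadPeak/gappedPeak-style intervals (external caller output)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            fold = float(parts[6]) if len(parts) > 6 else 1.0
            score = float(parts[7]) if len(parts) > 7 else 0.0
            peaks.append(
                Peak(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    fold_enrichment=fold if fold > 0 else 1.0,
                    score=score,
                )
            )
    return peaks
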