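"""Head-to-head RPM vs spike-in quantification of a treated/vehicle pair.

Global signal is the sum of value * length over a coverage track restricted
to target-genome chromosomes (the spike-in is the yardstick, not the
measurand). Replicates are scaled each by their own factor first, then
averaged; the condition ratio is the ratio of averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from chiprx.assign import AlignmentRecord, genome_of_chrom
from chiprx.spikenorm import ScalingResult
from chiprx.tracks import CoverageTrack, MetageneProfile, coverage_bedgraph, metagene_tss, peak_mean_coverage


def target_chroms(chrom_sizes: dict[str, int]) -> list[str]:
    return [c for c in chrom_sizes if genome_of_chrom(c) == "target"]


def global_signal(track: CoverageTrack, target_only: bool = True) -> float:
    """Genome-wide scaled signal: sum of value * length over the track.

    Restricted to target-genome chromosomes by default. Equals
    scale * total aligned bases by the track mass-conservation invariant.
    """
    if not track.intervals:
        warnings.warn(f"track {track.sample_id!r} is empty; global signal 0", stacklevel=2)
        return 0.0
    chroms = target_chroms(track.chrom_sizes) if target_only else None
    return track.total_signal(chroms)


@dataclass(frozen=True)
class ScaledSample:
    """One pulldown replicate: its alignments plus its scaling result."""

    alignments: Sequence[AlignmentRecord]
    scaling: ScalingResult
    chrom_sizes: dict[str, int]


@dataclass
class ComparisonReport:
    """Treated/vehicle comparison under spike-in and RPM normalization."""

    spikein_signal: dict[str, float]
    rpm_signal: dict[str, float]
    spikein_ratio: float
    rpm_ratio: float
    metagene: dict[str, dict[str, MetageneProfile]] = field(default_factory=dict)
    peak_coverage: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "spikein_signal": self.spikein_signal,
            "rpm_signal": self.rpm_signal,
            "spikein_ratio": self.spikein_ratio,
            "rpm_ratio": self.rpm_ratio,
            "peak_coverage": self.peak_coverage,
        }
        out["metagene"] = {
            norm: {
                cond: {
                    "offsets": prof.offsets.tolist(),
                    "values": prof.values.tolist(),
                    "n_sites": prof.n_sites,
                }
                for cond, prof in by_cond.items()
            }
            for norm, by_cond in self.metagene.items()
        }
        return out


def _condition_tracks(
    samples: Sequence[ScaledSample], normalization: str
) -> list[CoverageTrack]:
    tracks = []
    for s in samples:
        scale = (
            s.scaling.spikein_track_factor if normalization == "spikein" else s.scaling.rpm_factor
        )
        tracks.append(
            coverage_bedgraph(
                s.alignments,
                scale=scale,
                chrom_sizes=s.chrom_sizes,
                sample_id=s.scaling.sample_id,
                normalization=normalization,
            )
        )
    return tracks


def _mean_profile(profiles: list[MetageneProfile]) -> MetageneProfile:
    values = np.mean([p.values for p in profiles], axis=0)
    return MetageneProfile(
        offsets=profiles[0].offsets,
        values=values,
        n_sites=profiles[0].n_sites,
        bin_size=profiles[0].bin_size,
    )


def compare_conditions(
    treated: Sequence[ScaledSample],
    vehicle: Sequence[ScaledSample],
    tss: Sequence[tuple[str, int, str]] | None = None,
    peaks: Sequence[tuple[str, int, int]] | None = None,
    window: int = 2000,
    bin_size: int = 25,
) -> ComparisonReport:
    """Compare conditions under both normalizations.

    For each normalization: per-replicate tracks are built with that
    replicate's own factor, global target-genome signals averaged across
    replicates, and the treated/vehicle ratio of averages reported.
    Metagene and per-peak coverage tables are emitted when TSSs / peaks are
    supplied.
    """
    if not treated or not vehicle:
        raise ValueError("both conditions need at least one scaled pulldown")
    signals: dict[str, dict[str, float]] = {}
    metagene: dict[str, dict[str, MetageneProfile]] = {}
    peak_cov: dict[str, dict[str, float]] = {}
    for norm in ("spikein", "rpm"):
        signals[norm] = {}
        metagene[norm] = {}
        peak_cov[norm] = {}
        for cond, samples in (("treated", treated), ("vehicle", vehicle)):
            tracks = _condition_tracks(samples, norm)
            signals[norm][cond] = float(np.mean([global_signal(t) for t in tracks]))
            if tss:
                metagene[norm][cond] = _mean_profile(
                    [metagene_tss(t, tss, window=window, bin_size=bin_size) for t in tracks]
                )
            if peaks:
                peak_cov[norm][cond] = float(
                    np.mean([peak_mean_coverage(t, peaks)[1] for t in tracks])
                )
    return ComparisonReport(
        spikein_signal=signals["spikein"],
        rpm_signal=signals["rpm"],
        spikein_ratio=signals["spikein"]["treated"] / signals["spikein"]["vehicle"],
        rpm_ratio=signals["rpm"]["treated"] / signals["rpm"]["vehicle"],
        metagene={n: d for n, d in metagene.items() if d},
        peak_coverage={n: d for n, d in peak_cov.items() if d},
    )
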