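"""Sliding-window Poisson broad-peak caller.

Self-contained stand-in for an external broad-mode peak caller: pulldown
read-start counts in sliding windows are tested against a depth-matched
Poisson expectation from the input library, significant windows are merged
(adjacent/overlapping first, then across gaps up to ``merge_gap``) into
broad peaks. Peaks are features of the target genome; spike-in alignments
are excluded before calling. p-values are not multiplicity-corrected;
``alpha`` is strict instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from chiprx.assign import AlignmentRecord


@dataclass(frozen=True)
class PeakParams:
    window: int = 200
    step: int = 100
    alpha: float = 1e-5
    merge_gap: int = 1000
    min_reads: int = 5

    def __post_init__(self) -> None:
        if min(self.window, self.step, self.merge_gap, self.min_reads) <= 0:
            raise ValueError("peak-calling parameters must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class Peak:
    """A broad enriched region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    fold_enrichment: float
    score: float  # -log10 p of the best constituent window

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("peak end must exceed start")
        if self.fold_enrichment <= 0:
            raise ValueError("fold_enrichment must be > 0")


def _target_starts(alignments: Iterable[AlignmentRecord]) -> dict[str, np.ndarray]:
    per_chrom: dict[str, list[int]] = {}
    for a in alignments:
        if a.genome_label == "target":
            per_chrom.setdefault(a.chrom, []).append(a.start)
    return {c: np.sort(np.asarray(v)) for c, v in per_chrom.items()}


def _window_counts(starts: np.ndarray, w_starts: np.ndarray, window: int) -> np.ndarray:
    lo = np.searchsorted(starts, w_starts, side="left")
    hi = np.searchsorted(starts, w_starts + window, side="left")
    return hi - lo


def call_broad_peaks(
    pulldown_alignments: Sequence[AlignmentRecord],
    input_alignments: Sequence[AlignmentRecord],
    chrom_sizes: dict[str, int],
    params: PeakParams | None = None,
) -> list[Peak]:
    """Call broad peaks on the target genome.

    Per window: Poisson test of the pulldown read-start count against
    lambda = input window count * depth ratio, floored at the genome-average
    pseudorate. Windows with p < alpha and count >= min_reads are kept and
    merged into broad peaks. Deterministic given inputs.
    """
    params = params or PeakParams()
    pd_starts = _target_starts(pulldown_alignments)
    in_starts = _target_starts(input_alignments)
    n_pd = sum(len(v) for v in pd_starts.values())
    n_in = sum(len(v) for v in in_starts.values())
    if n_in == 0:
        raise ValueError("input library has no target-genome alignments: no background model")
    if n_pd == 0:
        return []
    depth_ratio = n_pd / n_in
    target_chroms = {
        c: size for c, size in chrom_sizes.items() if c in pd_starts or c in in_starts
    }
    genome_len = sum(target_chroms.values())
    pseudorate = n_pd * params.window / genome_len  # genome-average expectation

    peaks: list[Peak] = []
    empty = np.array([], dtype=np.int64)
    for chrom in sorted(target_chroms):
        size = target_chroms[chrom]
        w_starts = np.arange(0, max(size - params.window, 0) + 1, params.step)
        if len(w_starts) == 0:
            continue
        cnt_pd = _window_counts(pd_starts.get(chrom, empty), w_starts, params.window)
        cnt_in = _window_counts(in_starts.get(chrom, empty), w_starts, params.window)
        lam = np.maximum(cnt_in * depth_ratio, pseudorate)
        pvals = stats.poisson.sf(cnt_pd - 1, lam)
        sig = (pvals < params.alpha) & (cnt_pd >= params.min_reads)
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        neglogp = -np.log10(np.maximum(pvals, 1e-300))
        # merge overlapping/adjacent significant windows, then bridge gaps
        runs: list[list[int]] = [[idx[0]]]
        for i in idx[1:]:
            prev_end = w_starts[runs[-1][-1]] + params.window
            if w_starts[i] <= prev_end + params.merge_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        in_chrom = in_starts.get(chrom, empty)
        pd_chrom = pd_starts.get(chrom, empty)
        for run in runs:
            start = int(w_starts[run[0]])
            end = int(min(w_starts[run[-1]] + params.window, size))
            obs = int(
                np.searchsorted(pd_chrom, end, side="left")
                - np.searchsorted(pd_chrom, start, side="left")
            )
            exp_in = (
                np.searchsorted(in_chrom, end, side="left")
                - np.searchsorted(in_chrom, start, side="left")
            ) * depth_ratio
            expected = max(exp_in, pseudorate * (end - start) / params.window)
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=start,
                    end=end,
                    fold_enrichment=obs / expected if expected > 0 else float(obs),
                    score=float(neglogp[run].max()),
                )
            )
    return peaks


def merged_footprint(peaks: Iterable[Peak]) -> set[tuple[str, int]]:
    """Set of (chrom, base) covered by any peak; used for monotonicity checks."""
    out: set[tuple[str, int]] = set()
    for p in peaks:
        out.update((p.chrom, b) for b in range(p.start, p.end))
    return out
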