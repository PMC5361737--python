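"""Per-pulldown spike-in scaling factors.

The scale factor of a pulldown is the reciprocal of its input-corrected
spike-in reads-per-million: spike-in RPM of the pulldown divided by the
spike-in read fraction of the matched input. Dividing by the per-sample
input fraction cancels sample-to-sample spike-in pipetting variability;
any alternative correction differing by a constant across samples leaves
all between-sample comparisons unchanged.

Fractions are computed over uniquely aligned reads only, matching the
unique-mapping filter upstream. Fractions are stored in [0, 1]; reports
render percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

from chiprx.assign import CountSummary

RPM_SCALE = 1_000_000


@dataclass(frozen=True)
class ScalingResult:
    """Spike-in scaling for one pulldown library."""

    sample_id: str
    sf9_rpm_pulldown: float
    input_sf9_fraction: float
    corrected_sf9_rpm: float
    scale_factor: float
    rpm_factor: float

    def __post_init__(self) -> None:
        if not (self.sf9_rpm_pulldown > 0):
            raise ValueError("sf9_rpm_pulldown must be > 0")
        if not (0 < self.input_sf9_fraction <= 1):
            raise ValueError("input_sf9_fraction must lie in (0, 1]")
        if not (self.corrected_sf9_rpm > 0 and self.scale_factor > 0):
            raise ValueError("corrected rpm and scale factor must be > 0")
        if not (self.rpm_factor > 0):
            raise ValueError("rpm_factor must be > 0")
        if abs(self.scale_factor * self.corrected_sf9_rpm - 1.0) > 1e-9:
            raise ValueError("scale_factor must equal 1 / corrected_sf9_rpm")

    @property
    def spikein_track_factor(self) -> float:
        """Coverage multiplier for spike-in normalized tracks.

        The scale factor corrects depth-normalized coverage, so the track
        factor is scale_factor * rpm_factor. The resulting signal is
        proportional to n_target / n_spikein (corrected by the input
        fraction) and therefore invariant to sequencing depth.
        """
        return self.scale_factor * self.rpm_factor


def sf9_rpm(counts: CountSummary) -> float:
    """Spike-in reads per million total aligned reads."""
    if counts.n_aligned == 0:
        raise ValueError("no aligned reads: cannot compute spike-in RPM")
    return RPM_SCALE * counts.n_spikein / counts.n_aligned


def input_sf9_fraction(input_counts: CountSummary) -> float:
    """Fraction of an input library's aligned reads that are spike-in."""
    if input_counts.n_aligned == 0:
        raise ValueError("no aligned reads in input library")
    frac = input_counts.n_spikein / input_counts.n_aligned
    if frac == 0:
        raise ValueError("spike-in absent from input library: correction undefined")
    return frac


def scaling_factor(
    pulldown: CountSummary, matched_input: CountSummary, sample_id: str
) -> ScalingResult:
    """Input-corrected spike-in scale factor for one pulldown.

    corrected = sf9_rpm(pulldown) / input_sf9_fraction(matched_input);
    scale_factor = 1 / corrected. ``rpm_factor`` (1e6 / total aligned
    pulldown reads) is the plain depth normalizer used for comparison.
    """
    rpm = sf9_rpm(pulldown)
    frac = input_sf9_fraction(matched_input)
    corrected = rpm / frac
    if corrected == 0:
        raise ValueError("corrected spike-in RPM is zero: scale factor undefined")
    return ScalingResult(
        sample_id=sample_id,
        sf9_rpm_pulldown=rpm,
        input_sf9_fraction=frac,
        corrected_sf9_rpm=corrected,
        scale_factor=1.0 / corrected,
        rpm_factor=RPM_SCALE / pulldown.n_aligned,
    )
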