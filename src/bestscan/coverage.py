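"""Read-density computation: reads per kilobase per mapability.

The core normalized statistic everywhere in the package is

    density = count(anchors in window, resolved strand)
              / (window length / 1000)
              / mean mapability of the window

Sense/antisense resolve relative to the window's own strand: on a
plus-strand window, plus-strand reads are sense; on a minus-strand
window, minus-strand reads are sense.  A window whose mean mapability
falls at or below a configurable floor yields an *undefined* density
rather than a huge value; callers exclude such windows.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import GenomicInterval, MapabilityTrack, StrandedReadTrack

#: Mean mapability at or below this makes a window's density undefined.
DEFAULT_MAPABILITY_FLOOR = 0.05

STRAND_MODES = ("sense", "antisense", "plus", "minus")


@dataclass(frozen=True)
class DensityValue:
    """A reads/kb/mapability value; ``defined`` is False when the window's
    mapability was at or below the floor."""

    value: float
    defined: bool = True

    def __float__(self) -> float:
        if not self.defined:
            raise ValueError("undefined density (mapability below floor)")
        return self.value


UNDEFINED = DensityValue(float("nan"), defined=False)


def resolve_strand(window_strand: str, mode: str) -> str:
    """Map a strand mode to the read strand it selects for this window."""
    if mode == "plus":
        return "+"
    if mode == "minus":
        return "-"
    if mode not in ("sense", "antisense"):
        raise ValueError(f"unknown strand mode {mode!r}")
    if window_strand not in ("+", "-"):
        raise ValueError("sense/antisense requires a stranded window")
    if mode == "sense":
        return window_strand
    return "-" if window_strand == "+" else "+"


def window_density(
    track: StrandedReadTrack,
    window: GenomicInterval,
    strand_mode: str,
    mapability: MapabilityTrack,
    mapability_floor: float = DEFAULT_MAPABILITY_FLOOR,
) -> DensityValue:
    """Density of read anchors in ``window`` on the resolved strand."""
    read_strand = resolve_strand(window.strand, strand_mode)
    mean_map = mapability.mean(window.chrom, window.start, window.end)
    if mean_map <= mapability_floor:
        return UNDEFINED
    count = track.count(window.chrom, window.start, window.end, read_strand)
    return DensityValue(count / (window.length / 1000.0) / mean_map)


def binned_density_profile(
    track: StrandedReadTrack,
    region: GenomicInterval,
    bin_bp: int,
    strand_mode: str,
    mapability: MapabilityTrack,
    mapability_floor: float = DEFAULT_MAPABILITY_FLOOR,
    chrom_size: int | None = None,
) -> list[DensityValue]:
    """Densities in contiguous ``bin_bp`` bins tiling ``region`` left to
    right in genome coordinates.

    The last partial bin is kept and normalized by its own length.  Each
    anchor contributes to exactly one bin, so bin counts add up exactly
    to the whole-region count.  Bins that fall off the chromosome end
    (when ``chrom_size`` is given) are clipped out and reported as
    undefined.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if region.length < bin_bp:
        raise ValueError("region shorter than one bin")
    out: list[DensityValue] = []
    for lo in range(region.start, region.end, bin_bp):
        hi = min(lo + bin_bp, region.end)
        if chrom_size is not None and hi > chrom_size:
            out.append(UNDEFINED)
            continue
        sub = GenomicInterval(region.chrom, lo, hi, region.strand)
        out.append(window_density(track, sub, strand_mode, mapability, mapability_floor))
    return out
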