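"""Metaprofiles on proportional coordinates, peak categorization, and the
promoter-proximal pausing index.

Proportional distance rescales every region so its interior spans [0, 1]
regardless of length: a genomic offset x from the region start maps to
x / L.  Read densities are computed in fixed-size genomic bins (150 bp
by default) tiled across the peak and its flanks, normalized per region
by the region's average density, then aggregated across regions on a
fixed proportional grid.  For a 300-bp peak the first upstream bin spans
-0.5 to 0, the first interior bin 0 to 0.5, the second 0.5 to 1, and the
first downstream bin 1 to 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .classifier import IntervalMask
from .coverage import DEFAULT_MAPABILITY_FLOOR, window_density
from .io import (
    GenomicInterval,
    MapabilityTrack,
    PeakSet,
    StrandedReadTrack,
    Transcript,
)

TRANSCRIBED_INTRAGENIC = "transcribed-intragenic"
NONTRANSCRIBED_INTRAGENIC = "nontranscribed-intragenic"
INTERGENIC = "intergenic"

DEFAULT_FLANK_BP = 5000
DEFAULT_PROFILE_BIN_BP = 150
DEFAULT_PROFILE_EXCLUSION_BP = 2000

#: Fixed aggregation grid: proportional bins of width 0.1 spanning [-2, 3].
GRID_EDGES = np.round(np.arange(-2.0, 3.0 + 1e-9, 0.1), 10)


# ---------------------------------------------------------------------------
# Peak categorization and promoter filtering
# ---------------------------------------------------------------------------

def _transcript_tree(transcripts: list[Transcript]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in transcripts:
        trees.setdefault(t.chrom, IntervalTree()).addi(
            t.interval.start, t.interval.end, t.accession
        )
    return trees


def categorize_peak(
    peak: GenomicInterval,
    transcripts: list[Transcript] | dict[str, IntervalTree],
    active: set[str],
) -> str:
    """Place a peak among transcribed-intragenic, nontranscribed-intragenic
    or intergenic; a peak touching both active and inactive transcripts is
    transcribed-intragenic (active takes precedence)."""
    trees = (
        transcripts if isinstance(transcripts, dict) else _transcript_tree(transcripts)
    )
    tree = trees.get(peak.chrom)
    if tree is None:
        return INTERGENIC
    hits = tree.overlap(peak.start, peak.end)
    if not hits:
        return INTERGENIC
    if any(iv.data in active for iv in hits):
        return TRANSCRIBED_INTRAGENIC
    return NONTRANSCRIBED_INTRAGENIC


def filter_promoter_proximal(
    peaks: PeakSet,
    transcripts: list[Transcript],
    h3k4me3: PeakSet | None = None,
    flank_bp: int = DEFAULT_FLANK_BP,
    radius_bp: int = DEFAULT_PROFILE_EXCLUSION_BP,
) -> PeakSet:
    """Drop peaks whose peak+flank extension comes within ``radius_bp`` of
    any TSS, annotated gene end, or H3K4me3 peak."""
    if flank_bp < 0 or radius_bp < 0:
        raise ValueError("radii must be non-negative")
    ivs: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        for x in (t.tss, t.gene_end):
            ivs.setdefault(t.chrom, []).append((max(0, x - radius_bp), x + radius_bp + 1))
    if h3k4me3 is not None:
        for p in h3k4me3:
            ivs.setdefault(p.chrom, []).append(
                (max(0, p.start - radius_bp), p.end + radius_bp)
            )
    mask = IntervalMask(ivs)
    kept = [
        p
        for p in peaks
        if not mask.intersects(p.chrom, max(0, p.start - flank_bp), p.end + flank_bp)
    ]
    return PeakSet(name=peaks.name, peaks=kept)


# ---------------------------------------------------------------------------
# Proportional bins
# ---------------------------------------------------------------------------

UPSTREAM, INTERIOR, DOWNSTREAM = "upstream", "interior", "downstream"


@dataclass(frozen=True)
class ProportionalBin:
    """One genomic bin of a region profile with its proportional span."""

    start: int  # genomic, 0-based half-open
    end: int
    p_lo: float  # proportional coordinates: (offset from peak start) / L
    p_hi: float
    zone: str


def proportional_bins(
    peak: GenomicInterval,
    bin_bp: int = DEFAULT_PROFILE_BIN_BP,
    flank_bp: int = DEFAULT_FLANK_BP,
) -> list[ProportionalBin]:
    """Tile a peak and its flanks with ``bin_bp`` genomic bins and assign
    each its proportional-distance span.

    Upstream bins tile backwards from the peak start, interior bins
    forwards from the peak start, downstream bins forwards from the peak
    end; partial bins at the far edges (and at the interior end when the
    peak length is not a bin multiple) keep their own lengths.  The
    proportional coordinate of genomic position x is (x - start) / L.
    """
    if bin_bp <= 0 or flank_bp < 0:
        raise ValueError("bin_bp must be positive and flank_bp non-negative")
    L = peak.length
    bins: list[ProportionalBin] = []
    # upstream: backwards from peak.start, clipped at the chromosome origin
    lo_limit = max(0, peak.start - flank_bp)
    hi = peak.start
    upstream: list[ProportionalBin] = []
    while hi > lo_limit:
        lo = max(lo_limit, hi - bin_bp)
        upstream.append(
            ProportionalBin(lo, hi, (lo - peak.start) / L, (hi - peak.start) / L, UPSTREAM)
        )
        hi = lo
    bins.extend(reversed(upstream))
    for lo in range(peak.start, peak.end, bin_bp):
        hi = min(lo + bin_bp, peak.end)
        bins.append(
            ProportionalBin(lo, hi, (lo - peak.start) / L, (hi - peak.start) / L, INTERIOR)
        )
    for lo in range(peak.end, peak.end + flank_bp, bin_bp):
        hi = min(lo + bin_bp, peak.end + flank_bp)
        bins.append(
            ProportionalBin(lo, hi, (lo - peak.start) / L, (hi - peak.start) / L, DOWNSTREAM)
        )
    return bins


# ---------------------------------------------------------------------------
# Aggregated profiles
# ---------------------------------------------------------------------------

@dataclass
class ProportionalProfile:
    """Aggregated relative sense/antisense density on a fixed proportional
    grid.  ``n_regions`` counts the regions contributing to each bin."""

    edges: np.ndarray
    mean_sense: np.ndarray
    mean_antisense: np.ndarray
    n_regions: np.ndarray
    n_skipped: int = 0
    #: per-region (bins, relative sense, relative antisense), for diagnostics
    regions: list = field(default_factory=list, repr=False)


def _region_relative(
    densities: list[float], lengths: np.ndarray
) -> np.ndarray | None:
    d = np.asarray(densities)
    mean = float((d * lengths).sum() / lengths.sum())
    if mean <= 0:
        return None
    return d / mean


def _accumulate(
    grid_sum: np.ndarray,
    grid_n: np.ndarray,
    pbins: list[ProportionalBin],
    rel: np.ndarray,
    edges: np.ndarray,
) -> None:
    """Resample one region's piecewise-constant relative density onto the
    grid by proportional-overlap weighting, then count it once per touched
    grid bin."""
    n = edges.size - 1
    acc = np.zeros(n)
    wt = np.zeros(n)
    for pb, r in zip(pbins, rel):
        lo = np.searchsorted(edges, pb.p_lo, "right") - 1
        hi = np.searchsorted(edges, pb.p_hi, "left")
        for g in range(max(lo, 0), min(hi, n)):
            ov = min(pb.p_hi, edges[g + 1]) - max(pb.p_lo, edges[g])
            if ov > 0:
                acc[g] += ov * r
                wt[g] += ov
    touched = wt > 0
    grid_sum[touched] += acc[touched] / wt[touched]
    grid_n[touched] += 1


def proportional_profile(
    peaks: PeakSet,
    track: StrandedReadTrack,
    mapability: MapabilityTrack,
    flank_bp: int = DEFAULT_FLANK_BP,
    bin_bp: int = DEFAULT_PROFILE_BIN_BP,
    grid_edges: np.ndarray = GRID_EDGES,
    mapability_floor: float = DEFAULT_MAPABILITY_FLOOR,
) -> ProportionalProfile:
    """Aggregate relative sense/antisense density over a peak set on the
    proportional axis.

    Unstranded peaks use plus-strand reads as "sense/plus" and
    minus-strand reads as antisense.  Each region is normalized per
    strand by its own length-weighted mean bin density; regions with an
    undefined bin (low mapability or off-chromosome flank) or zero
    density on either strand are skipped and counted.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks to profile")
    edges = np.asarray(grid_edges, dtype=float)
    n = edges.size - 1
    sums = {s: np.zeros(n) for s in ("sense", "antisense")}
    counts = np.zeros(n, dtype=np.int64)
    skipped = 0
    kept_regions = []
    for peak in peaks:
        if peak.start - flank_bp < 0:
            skipped += 1
            continue
        pbins = proportional_bins(peak, bin_bp, flank_bp)
        lengths = np.array([b.end - b.start for b in pbins], dtype=float)
        rels: dict[str, np.ndarray] = {}
        ok = True
        for mode_label, read_strand in (("sense", "+"), ("antisense", "-")):
            dens: list[float] = []
            for b in pbins:
                d = window_density(
                    track,
                    GenomicInterval(peak.chrom, b.start, b.end),
                    "plus" if read_strand == "+" else "minus",
                    mapability,
                    mapability_floor,
                )
                if not d.defined:
                    ok = False
                    break
                dens.append(d.value)
            if not ok:
                break
            rel = _region_relative(dens, lengths)
            if rel is None:
                ok = False
                break
            rels[mode_label] = rel
        if not ok:
            skipped += 1
            continue
        counts_before = counts.copy()
        _accumulate(sums["sense"], counts, pbins, rels["sense"], edges)
        _accumulate(sums["antisense"], counts_before, pbins, rels["antisense"], edges)
        kept_regions.append((pbins, rels["sense"], rels["antisense"]))
    with np.errstate(invalid="ignore"):
        mean_s = np.where(counts > 0, sums["sense"] / np.maximum(counts, 1), 0.0)
        mean_a = np.where(counts > 0, sums["antisense"] / np.maximum(counts, 1), 0.0)
    return ProportionalProfile(
        edges=edges,
        mean_sense=mean_s,
        mean_antisense=mean_a,
        n_regions=counts,
        n_skipped=skipped,
        regions=kept_regions,
    )


def gene_metaprofile(
    active: list[Transcript],
    track: StrandedReadTrack,
    mapability: MapabilityTrack,
    n_bins: int = 40,
    flank_fraction: float = 0.5,
    mapability_floor: float = DEFAULT_MAPABILITY_FLOOR,
) -> ProportionalProfile:
    """Strand-aware metaprofile over gene bodies: TSS maps to 0, the gene
    end to 1, flanks extend ``flank_fraction`` gene lengths on each side.

    Per transcript and strand the density profile is normalized by its
    own mean; transcripts whose extended span leaves the chromosome or
    has zero sense or antisense signal are skipped.
    """
    if not active:
        raise ValueError("no active transcripts")
    edges = np.linspace(-flank_fraction, 1.0 + flank_fraction, n_bins + 1)
    n = edges.size - 1
    sum_s = np.zeros(n)
    sum_a = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    skipped = 0
    for t in active:
        L = t.length
        iv = t.interval
        # integer genomic boundaries for each proportional grid edge
        if t.strand == "+":
            bounds = [iv.start + int(round(x * L)) for x in edges]
        else:
            bounds = [iv.end - int(round(x * L)) for x in edges]  # descending
        ok = True
        dens_s: list[float] = []
        dens_a: list[float] = []
        for k in range(n):
            lo, hi = sorted((bounds[k], bounds[k + 1]))
            if lo < 0 or lo == hi:
                ok = False
                break
            win = GenomicInterval(t.chrom, lo, hi, t.strand)
            ds = window_density(track, win, "sense", mapability, mapability_floor)
            da = window_density(track, win, "antisense", mapability, mapability_floor)
            if not (ds.defined and da.defined):
                ok = False
                break
            dens_s.append(ds.value)
            dens_a.append(da.value)
        if not ok:
            skipped += 1
            continue
        ms, ma = float(np.mean(dens_s)), float(np.mean(dens_a))
        if ms <= 0 or ma <= 0:
            skipped += 1
            continue
        sum_s += np.asarray(dens_s) / ms
        sum_a += np.asarray(dens_a) / ma
        counts += 1
    mean_s = np.where(counts > 0, sum_s / np.maximum(counts, 1), 0.0)
    mean_a = np.where(counts > 0, sum_a / np.maximum(counts, 1), 0.0)
    return ProportionalProfile(
        edges=edges,
        mean_sense=mean_s,
        mean_antisense=mean_a,
        n_regions=counts,
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# Pausing index
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PausingIndexResult:
    accession: str
    promoter_density: float
    body_density: float
    index: float
    defined: bool


def pausing_index(
    t: Transcript,
    track: StrandedReadTrack,
    mapability: MapabilityTrack,
    promoter_window_bp: int = 1000,
    body_offset_bp: int = 1000,
    mapability_floor: float = DEFAULT_MAPABILITY_FLOOR,
) -> PausingIndexResult:
    """Ratio of promoter-proximal to gene-body sense read density.

    The promoter window is the first ``promoter_window_bp`` bases
    downstream of the TSS on the transcript strand; the body runs from
    TSS + ``body_offset_bp`` to the gene end.  High values indicate
    promoter-proximal polymerase stalling.
    """
    if t.length <= promoter_window_bp + body_offset_bp:
        raise ValueError(
            f"{t.accession}: transcript too short for pausing index "
            f"({t.length} bp <= {promoter_window_bp + body_offset_bp})"
        )
    iv = t.interval
    if t.strand == "+":
        prom = GenomicInterval(iv.chrom, iv.start, iv.start + promoter_window_bp, "+")
        body = GenomicInterval(iv.chrom, iv.start + body_offset_bp, iv.end, "+")
    else:
        prom = GenomicInterval(iv.chrom, iv.end - promoter_window_bp, iv.end, "-")
        body = GenomicInterval(iv.chrom, iv.start, iv.end - body_offset_bp, "-")
    dp = window_density(track, prom, "sense", mapability, mapability_floor)
    db = window_density(track, body, "sense", mapability, mapability_floor)
    if not (dp.defined and db.defined) or db.value == 0:
        return PausingIndexResult(t.accession, getattr(dp, "value", float("nan")),
                                  getattr(db, "value", float("nan")), float("nan"), False)
    return PausingIndexResult(t.accession, dp.value, db.value, dp.value / db.value, True)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_profile(profile: ProportionalProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("bin_low\tbin_high\tmean_sense\tmean_antisense\tn_regions\n")
        for k in range(profile.edges.size - 1):
            fh.write(
                f"{profile.edges[k]:.4f}\t{profile.edges[k + 1]:.4f}\t"
                f"{profile.mean_sense[k]:.6f}\t{profile.mean_antisense[k]:.6f}\t"
                f"{int(profile.n_regions[k])}\n"
            )


def write_pausing_report(results: list[PausingIndexResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tpromoter_density\tbody_density\tindex\n")
        for r in results:
            idx = f"{r.index:.6g}" if r.defined else "NA"
            fh.write(
                f"{r.accession}\t{r.promoter_density:.6g}\t{r.body_density:.6g}\t{idx}\n"
            )
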