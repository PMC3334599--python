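"""Overlap enrichment of predictions with peak sets, and input-normalized
chromatin-mark representation at predicted loci.

Co-occurrence is measured against seeded random background windows drawn
from the same non-promoter search space: fold = observed overlap
frequency / background overlap frequency, with a two-tailed Pearson
chi-squared test (df = 1, no continuity correction) on the 2x2 table.

Mark representation normalizes a ChIP-seq track twice: read density
(reads/bp, pooled over regions) at predicted loci over background, then
that enrichment over the same ratio for the sequencing input:

    ln_fold = ln[ (treat@loci / treat@bg) / (input@loci / input@bg) ]
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .classifier import IntervalMask
from .io import GenomicInterval, PeakSet, StrandedReadTrack


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows = (predictions, background), cols = (overlap, no overlap)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class EnrichmentResult:
    peak_set: str
    fold: float
    chi2: float
    p: float
    observed_fraction: float
    background_fraction: float
    n_obs: int
    n_bg: int


@dataclass(frozen=True)
class MarkRepresentation:
    mark: str
    ln_fold: float
    defined: bool
    replicate_ln_folds: tuple[float, ...] = ()
    sd: float = float("nan")


def sample_background_windows(
    n: int,
    window_bp: int,
    mask: IntervalMask,
    chrom_sizes: dict[str, int],
    seed: int,
    extra_exclusions: PeakSet | None = None,
    max_tries_per_window: int = 1000,
) -> list[GenomicInterval]:
    """Seeded uniform-random windows disjoint from the exclusion mask
    (and any extra excluded peaks)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    extra = None
    if extra_exclusions is not None:
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in extra_exclusions:
            per_chrom.setdefault(p.chrom, []).append((p.start, p.end))
        extra = IntervalMask(per_chrom)
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[GenomicInterval] = []
    for i in range(n):
        for _ in range(max_tries_per_window):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            limit = chrom_sizes[chrom] - window_bp
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit + 1))
            end = start + window_bp
            if mask.intersects(chrom, start, end):
                continue
            if extra is not None and extra.intersects(chrom, start, end):
                continue
            out.append(GenomicInterval(chrom, start, end))
            break
        else:
            raise RuntimeError(
                f"could not place background window {i + 1}/{n} after "
                f"{max_tries_per_window} tries ({len(out)} placed)"
            )
    return out


def _peak_tree(peaks: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def overlap_fraction(
    windows: list[GenomicInterval], peaks: PeakSet, min_overlap_bp: int = 1
) -> float:
    """Fraction of windows sharing >= min_overlap_bp with any peak."""
    if not windows:
        raise ValueError("no windows")
    trees = _peak_tree(peaks)
    hit = 0
    for w in windows:
        tree = trees.get(w.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(w.start, w.end):
            if min(iv.end, w.end) - max(iv.begin, w.start) >= min_overlap_bp:
                hit += 1
                break
    return hit / len(windows)


def chi_squared_2x2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared (df=1, no continuity correction) and its
    two-tailed p-value."""
    obs = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero marginal in contingency table")
    expected = np.outer(rows, cols) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def peak_overlap_enrichment(
    predictions: list[GenomicInterval],
    background: list[GenomicInterval],
    peaks: PeakSet,
    min_overlap_bp: int = 1,
) -> EnrichmentResult:
    """Fold enrichment (observed over background overlap frequency) with
    the chi-squared test on the underlying 2x2 counts."""
    f_obs = overlap_fraction(predictions, peaks, min_overlap_bp)
    f_bg = overlap_fraction(background, peaks, min_overlap_bp)
    n_obs, n_bg = len(predictions), len(background)
    a = round(f_obs * n_obs)
    c = round(f_bg * n_bg)
    chi2, p = chi_squared_2x2(ContingencyTable2x2(a, n_obs - a, c, n_bg - c))
    fold = f_obs / f_bg if f_bg > 0 else math.inf
    return EnrichmentResult(
        peak_set=peaks.name, fold=fold, chi2=chi2, p=p,
        observed_fraction=f_obs, background_fraction=f_bg, n_obs=n_obs, n_bg=n_bg,
    )


def _pooled_density_per_bp(
    track: StrandedReadTrack, regions: list[GenomicInterval]
) -> float:
    """Total reads (both strands) over total bp, pooled across regions."""
    reads = 0
    bp = 0
    for r in regions:
        reads += track.count(r.chrom, r.start, r.end, "+")
        reads += track.count(r.chrom, r.start, r.end, "-")
        bp += r.length
    if bp == 0:
        raise ValueError("zero total region length")
    return reads / bp


def mark_representation(
    treatment: StrandedReadTrack,
    input_track: StrandedReadTrack,
    loci: list[GenomicInterval],
    background: list[GenomicInterval],
    mark: str = "",
) -> MarkRepresentation:
    """Input-normalized ln fold enrichment of a mark at predicted loci."""
    t_loci = _pooled_density_per_bp(treatment, loci)
    t_bg = _pooled_density_per_bp(treatment, background)
    i_loci = _pooled_density_per_bp(input_track, loci)
    i_bg = _pooled_density_per_bp(input_track, background)
    if min(t_loci, t_bg, i_loci, i_bg) <= 0:
        return MarkRepresentation(mark=mark, ln_fold=float("nan"), defined=False)
    ln_fold = math.log((t_loci / t_bg) / (i_loci / i_bg))
    return MarkRepresentation(mark=mark, ln_fold=ln_fold, defined=True)


def mark_representation_replicates(
    treatments: list[StrandedReadTrack],
    input_tracks: list[StrandedReadTrack],
    loci: list[GenomicInterval],
    background: list[GenomicInterval],
    mark: str = "",
) -> MarkRepresentation:
    """Per-replicate ln folds with their mean and standard deviation."""
    reps = [
        mark_representation(t, i, loci, background, mark)
        for t, i in zip(treatments, input_tracks)
    ]
    vals = [r.ln_fold for r in reps if r.defined]
    if not vals:
        return MarkRepresentation(mark=mark, ln_fold=float("nan"), defined=False)
    return MarkRepresentation(
        mark=mark,
        ln_fold=float(np.mean(vals)),
        defined=True,
        replicate_ln_folds=tuple(vals),
        sd=float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
    )


def write_enrichment_report(results: list[EnrichmentResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("peak_set\tn_obs\tn_bg\tobs_fraction\tbg_fraction\tfold\tchi2\tp\n")
        for r in results:
            fh.write(
                f"{r.peak_set}\t{r.n_obs}\t{r.n_bg}\t{r.observed_fraction:.6f}\t"
                f"{r.background_fraction:.6f}\t{r.fold:.4f}\t{r.chi2:.4f}\t{r.p:.4g}\n"
            )
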