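"""Three-class Naïve Bayes classifier for BEST detection.

The signature of promoter-proximal polymerase pausing — bidirectional
expression of short transcripts (BEST) — is learned from active
promoters and searched for genome-wide in non-promoter 2-kb windows.

Classes: B (BEST), E (transcriptional elongation), N (non-transcribed).
Training windows are 2-kb windows centered on active TSSs (B), on
midpoints of active transcripts (E), and on midpoints of randomly
selected intergenic regions length-matched to active transcripts (N).

Six features per stranded window:

    f1  sense read density (reads/kb/mapability)
    f2  antisense read density
    f3  f1 relative to the sense density in the 2-kb window immediately 3'
    f4  f2 relative to the antisense density immediately 3'
    f5  f1 relative to the sense density immediately 5'
    f6  f2 relative to the antisense density immediately 5'

(3'/5' are strand-relative; ratios are regularized with a symmetric
pseudocount in numerator and denominator.)  Class-conditional feature
distributions are quantile-binned histograms of log1p-transformed
values with Laplace smoothing; priors are equal.  Windows are assigned

    class = argmax_{c in {B,E,N}}  Pr(c) prod_j Pr(f_j | c)

and scored with the natural-log odds of B against the better of E and N:

    LOD(B) = ln [ Pr(B) prod_j Pr(f_j|B)
                  / max_{c in {E,N}} Pr(c) prod_j Pr(f_j|c) ]

Windows with LOD > 2.5 on one or both strands are high-confidence BEST
loci.  The genome scan avoids promoters and gene ends: any 2-kb window
within 7 kb of a TSS, an annotated gene end, or an H3K4me3 peak is
excluded (as are its two flanking windows, which the ratio features
need).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .coverage import DEFAULT_MAPABILITY_FLOOR, window_density
from .io import (
    GenomicInterval,
    MapabilityTrack,
    PeakSet,
    StrandedReadTrack,
    Transcript,
    WindowPrediction,
)

logger = logging.getLogger(__name__)

CLASSES = ("B", "E", "N")
DEFAULT_WINDOW_BP = 2000
DEFAULT_EXCLUSION_RADIUS_BP = 7000
DEFAULT_LOD_THRESHOLD = 2.5
DEFAULT_N_BINS = 20
DEFAULT_BIN_PSEUDOCOUNT = 1.0
DEFAULT_RATIO_PSEUDOCOUNT = 0.1
DEFAULT_MIN_CLASS_SIZE = 50

MODEL_FORMAT_VERSION = 1


class FeatureUndefinedError(ValueError):
    """A window or one of its flanks has undefined density (low
    mapability) or falls off the chromosome; the caller skips it."""


@dataclass(frozen=True)
class FeatureVector:
    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4, self.f5, self.f6])


# ---------------------------------------------------------------------------
# Exclusion mask
# ---------------------------------------------------------------------------

class IntervalMask:
    """Merged, sorted exclusion intervals per chromosome with O(log n)
    intersection queries."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]] | None = None):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, ivs in intervals.items():
                merged = _merge(ivs)
                self._starts[chrom] = np.array([s for s, _ in merged], dtype=np.int64)
                self._ends[chrom] = np.array([e for _, e in merged], dtype=np.int64)

    def intersects(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None:
            return False
        idx = int(np.searchsorted(starts, end, "left"))
        return idx > 0 and int(self._ends[chrom][idx - 1]) > start

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        if chrom not in self._starts:
            return []
        return list(zip(self._starts[chrom].tolist(), self._ends[chrom].tolist()))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)


def _merge(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def exclusion_mask(
    transcripts: list[Transcript],
    h3k4me3: PeakSet | None = None,
    radius_bp: int = DEFAULT_EXCLUSION_RADIUS_BP,
) -> IntervalMask:
    """Union of ``radius_bp`` neighborhoods around every TSS, every
    annotated gene end, and every H3K4me3 peak."""
    if radius_bp < 0:
        raise ValueError("radius must be non-negative")
    ivs: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        for x in (t.tss, t.gene_end):
            ivs.setdefault(t.chrom, []).append((max(0, x - radius_bp), x + radius_bp))
    if h3k4me3 is not None:
        for p in h3k4me3:
            ivs.setdefault(p.chrom, []).append(
                (max(0, p.start - radius_bp), p.end + radius_bp)
            )
    return IntervalMask(ivs)


# ---------------------------------------------------------------------------
# Training windows
# ---------------------------------------------------------------------------

def _centered_window(chrom: str, center: int, strand: str, window_bp: int,
                     chrom_size: int) -> GenomicInterval | None:
    half = window_bp // 2
    start, end = center - half, center + half
    if start < 0 or end > chrom_size:
        return None
    return GenomicInterval(chrom, start, end, strand)


def sample_intergenic_regions(
    transcripts: list[Transcript],
    lengths: list[int],
    chrom_sizes: dict[str, int],
    n: int,
    rng: np.random.Generator,
    max_tries_per_region: int = 200,
) -> list[GenomicInterval]:
    """Random regions matched to ``lengths`` (sampled with replacement)
    that overlap no known transcript."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        per_chrom.setdefault(t.chrom, []).append((t.interval.start, t.interval.end))
    mask = IntervalMask(per_chrom)
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[GenomicInterval] = []
    lengths_a = np.asarray(lengths, dtype=np.int64)
    for i in range(n):
        length = int(rng.choice(lengths_a))
        placed = False
        for _ in range(max_tries_per_region):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            limit = chrom_sizes[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            if not mask.intersects(chrom, start, start + length):
                out.append(GenomicInterval(chrom, start, start + length))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place intergenic region {i + 1}/{n} after "
                f"{max_tries_per_region} tries ({len(out)} placed)"
            )
    return out


def build_training_windows(
    active: list[Transcript],
    chrom_sizes: dict[str, int],
    n_intergenic: int | None = None,
    seed: int = 0,
    window_bp: int = DEFAULT_WINDOW_BP,
    all_transcripts: list[Transcript] | None = None,
) -> dict[str, list[GenomicInterval]]:
    """2-kb training windows per class.

    B: centered on active TSSs; E: centered on active-transcript
    midpoints (both on the transcript strand); N: centered on midpoints
    of seeded random intergenic regions, length-matched to the active
    transcripts and overlapping no known transcript, with strands drawn
    uniformly (background is strand-symmetric).
    """
    if not active:
        raise ValueError("no active transcripts to train on")
    rng = np.random.default_rng(seed)
    windows: dict[str, list[GenomicInterval]] = {"B": [], "E": [], "N": []}
    for t in active:
        size = chrom_sizes[t.chrom]
        b = _centered_window(t.chrom, t.tss, t.strand, window_bp, size)
        e = _centered_window(t.chrom, t.interval.midpoint, t.strand, window_bp, size)
        if b is not None:
            windows["B"].append(b)
        if e is not None:
            windows["E"].append(e)
    if n_intergenic is None:
        n_intergenic = len(active)
    regions = sample_intergenic_regions(
        all_transcripts if all_transcripts is not None else active,
        [t.length for t in active],
        chrom_sizes,
        n_intergenic,
        rng,
    )
    strands = rng.choice(["+", "-"], size=len(regions))
    for region, strand in zip(regions, strands):
        w = _centered_window(
            region.chrom, region.midpoint, str(strand), window_bp, chrom_sizes[region.chrom]
        )
        if w is not None:
            windows["N"].append(w)
    return windows


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(
    track: StrandedReadTrack,
    window: GenomicInterval,
    mapability: MapabilityTrack,
    ratio_pseudocount: float = DEFAULT_RATIO_PSEUDOCOUNT,
    chrom_size: int | None = None,
    mapability_floor: float = DEFAULT_MAPABILITY_FLOOR,
) -> FeatureVector:
    """Six-feature vector for a stranded window; raises
    :class:`FeatureUndefinedError` when the window or a flank is
    unusable."""
    if window.strand not in ("+", "-"):
        raise ValueError("feature extraction needs a stranded window")
    w = window.length
    left_start = window.start - w
    right_end = window.end + w
    if left_start < 0 or (chrom_size is not None and right_end > chrom_size):
        raise FeatureUndefinedError("flanking window off chromosome")
    left = GenomicInterval(window.chrom, left_start, window.start, window.strand)
    right = GenomicInterval(window.chrom, window.end, right_end, window.strand)
    # 3' of a plus-strand window is the right neighbor; of a minus-strand
    # window the left neighbor.
    three_prime, five_prime = (right, left) if window.strand == "+" else (left, right)

    def dens(iv: GenomicInterval, mode: str) -> float:
        d = window_density(track, iv, mode, mapability, mapability_floor)
        if not d.defined:
            raise FeatureUndefinedError(f"undefined density in {iv}")
        return d.value

    f1 = dens(window, "sense")
    f2 = dens(window, "antisense")
    pc = ratio_pseudocount

    def ratio(num: float, den: float) -> float:
        # 0/0 (possible only at pseudocount 0) counts as equality
        if den + pc == 0.0:
            if num + pc == 0.0:
                return 1.0
            raise FeatureUndefinedError("infinite density ratio at zero pseudocount")
        return (num + pc) / (den + pc)

    f3 = ratio(f1, dens(three_prime, "sense"))
    f4 = ratio(f2, dens(three_prime, "antisense"))
    f5 = ratio(f1, dens(five_prime, "sense"))
    f6 = ratio(f2, dens(five_prime, "antisense"))
    return FeatureVector(f1, f2, f3, f4, f5, f6)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _smoothed_histogram(
    values: np.ndarray, interior_edges: np.ndarray, n_bins: int, pseudocount: float
) -> np.ndarray:
    """Laplace-smoothed bin masses: (count + pc) / (n + n_bins * pc).
    ``interior_edges`` are the n_bins-1 inner boundaries; values outside
    fall in the two edge bins."""
    idx = np.searchsorted(interior_edges, values, "right")
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    masses = (counts + pseudocount) / (values.size + n_bins * pseudocount)
    return masses


class ClassConditionalModel:
    """Per-class, per-feature smoothed binned distributions plus priors.

    Bin edges are quantiles of the pooled (all-class) log1p-transformed
    feature values, so every class is histogrammed on a common grid per
    feature.  A feature value outside the grid clamps to the nearest
    edge bin.
    """

    def __init__(
        self,
        priors: dict[str, float],
        interior_edges: list[np.ndarray],
        masses: dict[str, list[np.ndarray]],
        n_bins: int,
        pseudocount: float,
        ratio_pseudocount: float,
        transform: str = "log1p",
    ):
        self.priors = dict(priors)
        self.interior_edges = [np.asarray(e, dtype=float) for e in interior_edges]
        self.masses = {c: [np.asarray(m, dtype=float) for m in ms] for c, ms in masses.items()}
        self.n_bins = n_bins
        self.pseudocount = pseudocount
        self.ratio_pseudocount = ratio_pseudocount
        self.transform = transform
        self._log_priors = {c: np.log(p) for c, p in self.priors.items()}
        self._log_masses = {c: [np.log(m) for m in ms] for c, ms in self.masses.items()}
        self._check()

    def _check(self) -> None:
        if abs(sum(self.priors.values()) - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        for c in CLASSES:
            for j, m in enumerate(self.masses[c]):
                if abs(m.sum() - 1.0) > 1e-9:
                    raise ValueError(f"masses for ({c}, f{j + 1}) do not sum to 1")
                if (m <= 0).any():
                    raise ValueError(f"unsmoothed zero mass in ({c}, f{j + 1})")

    # -- scoring ----------------------------------------------------------

    def _transformed(self, fv: FeatureVector) -> np.ndarray:
        x = fv.as_array()
        if self.transform == "log1p":
            return np.log1p(x)
        if self.transform == "identity":
            return x
        raise ValueError(f"unknown transform {self.transform!r}")

    def log_likelihoods(self, fv: FeatureVector) -> dict[str, float]:
        """log [ Pr(c) prod_j Pr(f_j | c) ] per class."""
        x = self._transformed(fv)
        out = {}
        for c in CLASSES:
            ll = self._log_priors[c]
            for j in range(6):
                b = int(np.searchsorted(self.interior_edges[j], x[j], "right"))
                ll += self._log_masses[c][j][b]
            out[c] = ll
        return out

    def posterior(self, fv: FeatureVector) -> tuple[tuple[float, float, float], str]:
        """Normalized posteriors (B, E, N) and the argmax class; exact
        ties prefer N, then E, then B."""
        ll = self.log_likelihoods(fv)
        arr = np.array([ll[c] for c in CLASSES])
        m = arr.max()
        w = np.exp(arr - m)
        post = w / w.sum()
        tie_order = ("N", "E", "B")
        label = max(tie_order, key=lambda c: (ll[c], -tie_order.index(c)))
        return (float(post[0]), float(post[1]), float(post[2])), label

    def lod(self, fv: FeatureVector) -> float:
        """Natural-log odds of B against the better of E and N."""
        ll = self.log_likelihoods(fv)
        return ll["B"] - max(ll["E"], ll["N"])

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "priors": self.priors,
            "transform": self.transform,
            "n_bins": self.n_bins,
            "pseudocount": self.pseudocount,
            "ratio_pseudocount": self.ratio_pseudocount,
            "interior_edges": [e.tolist() for e in self.interior_edges],
            "masses": {c: [m.tolist() for m in ms] for c, ms in self.masses.items()},
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ClassConditionalModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {d.get('format_version')!r}")
        return cls(
            priors=d["priors"],
            interior_edges=[np.array(e) for e in d["interior_edges"]],
            masses={c: [np.array(m) for m in ms] for c, ms in d["masses"].items()},
            n_bins=d["n_bins"],
            pseudocount=d["pseudocount"],
            ratio_pseudocount=d["ratio_pseudocount"],
            transform=d["transform"],
        )

    @classmethod
    def load(cls, path: str) -> "ClassConditionalModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_model(
    training: dict[str, list[FeatureVector]],
    n_bins: int = DEFAULT_N_BINS,
    pseudocount: float = DEFAULT_BIN_PSEUDOCOUNT,
    ratio_pseudocount: float = DEFAULT_RATIO_PSEUDOCOUNT,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> ClassConditionalModel:
    """Fit the class-conditional histograms from labeled feature vectors.

    Per feature, values are log1p-transformed and binned into ``n_bins``
    quantile bins computed over the pooled all-class values; per-class
    masses get Laplace smoothing with ``pseudocount``.  Priors are equal
    (1/3 each).
    """
    for c in CLASSES:
        if len(training.get(c, [])) < min_class_size:
            raise ValueError(
                f"class {c} has {len(training.get(c, []))} training windows; "
                f"need >= {min_class_size}"
            )
    mats = {c: np.array([fv.as_array() for fv in training[c]]) for c in CLASSES}
    tmats = {c: np.log1p(m) for c, m in mats.items()}
    interior_edges: list[np.ndarray] = []
    masses: dict[str, list[np.ndarray]] = {c: [] for c in CLASSES}
    for j in range(6):
        pooled = np.concatenate([tmats[c][:, j] for c in CLASSES])
        qs = np.quantile(pooled, np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(qs)  # duplicated quantiles collapse bins
        eff_bins = edges.size + 1
        interior_edges.append(edges)
        for c in CLASSES:
            masses[c].append(
                _smoothed_histogram(tmats[c][:, j], edges, eff_bins, pseudocount)
            )
    return ClassConditionalModel(
        priors={c: 1.0 / 3.0 for c in CLASSES},
        interior_edges=interior_edges,
        masses=masses,
        n_bins=n_bins,
        pseudocount=pseudocount,
        ratio_pseudocount=ratio_pseudocount,
    )


def extract_training_features(
    windows: dict[str, list[GenomicInterval]],
    track: StrandedReadTrack,
    mapability: MapabilityTrack,
    chrom_sizes: dict[str, int],
    ratio_pseudocount: float = DEFAULT_RATIO_PSEUDOCOUNT,
    mapability_floor: float = DEFAULT_MAPABILITY_FLOOR,
) -> dict[str, list[FeatureVector]]:
    """Feature vectors per class, silently skipping unusable windows."""
    out: dict[str, list[FeatureVector]] = {c: [] for c in windows}
    for c, wins in windows.items():
        skipped = 0
        for w in wins:
            try:
                out[c].append(
                    extract_features(
                        track, w, mapability, ratio_pseudocount,
                        chrom_sizes.get(w.chrom), mapability_floor,
                    )
                )
            except FeatureUndefinedError:
                skipped += 1
        if skipped:
            logger.info("class %s: skipped %d/%d unusable windows", c, skipped, len(wins))
    return out


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

def scan_genome(
    model: ClassConditionalModel,
    track: StrandedReadTrack,
    mapability: MapabilityTrack,
    mask: IntervalMask,
    chrom_sizes: dict[str, int],
    window_bp: int = DEFAULT_WINDOW_BP,
    lod_threshold: float = DEFAULT_LOD_THRESHOLD,
    mapability_floor: float = DEFAULT_MAPABILITY_FLOOR,
) -> list[WindowPrediction]:
    """Scan non-overlapping ``window_bp`` windows (tiled from coordinate 0
    on every chromosome) on both strands.

    A window is skipped when it or either flanking window intersects the
    exclusion mask, falls off the chromosome, or has undefined density.
    Each surviving genomic window yields one prediction carrying its
    max-LOD strand; ``high_confidence`` is LOD > threshold on one or
    both strands.
    """
    predictions: list[WindowPrediction] = []
    n_masked = n_undefined = n_scored = 0
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for start in range(0, size - window_bp + 1, window_bp):
            end = start + window_bp
            if start - window_bp < 0 or end + window_bp > size:
                continue
            if mask.intersects(chrom, start - window_bp, end + window_bp):
                n_masked += 1
                continue
            best: tuple[float, tuple, str, str] | None = None
            try:
                for strand in ("+", "-"):
                    w = GenomicInterval(chrom, start, end, strand)
                    fv = extract_features(
                        track, w, mapability, model.ratio_pseudocount, size,
                        mapability_floor,
                    )
                    lod = model.lod(fv)
                    post, label = model.posterior(fv)
                    if best is None or lod > best[0]:
                        best = (lod, post, label, strand)
            except FeatureUndefinedError:
                n_undefined += 1
                continue
            lod, post, label, strand = best
            n_scored += 1
            predictions.append(
                WindowPrediction(
                    window=GenomicInterval(chrom, start, end, strand),
                    label=label,
                    posteriors=post,
                    lod=lod,
                    high_confidence=lod > lod_threshold,
                )
            )
    logger.info(
        "scan: %d windows scored, %d masked, %d undefined", n_scored, n_masked, n_undefined
    )
    return predictions
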