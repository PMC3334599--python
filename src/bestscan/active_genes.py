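"""Calling transcriptionally active transcripts.

A transcript's activity is measured as the sense-strand
reads/kb/mapability over its *body* — from 1 kb downstream of the TSS
to the annotated gene end, skipping the promoter-proximal pause peak.
Only transcripts longer than 3 kb carry a body.  The activity cutoff is
chosen by maximal accuracy against a labeled set of expressed and
non-expressed genes:

    accuracy(c) = (expressed with density >= c  +  non-expressed with
                   density < c) / all labeled genes

maximized over every observed density value (plus one value above the
maximum, the all-negative rule).  A transcript is called active when
its density is >= the cutoff (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coverage import DensityValue, window_density
from .io import GenomicInterval, MapabilityTrack, StrandedReadTrack, Transcript

DEFAULT_BODY_OFFSET_BP = 1000
DEFAULT_MIN_TRANSCRIPT_BP = 3000


def transcript_body(
    t: Transcript,
    offset_bp: int = DEFAULT_BODY_OFFSET_BP,
    min_len_bp: int = DEFAULT_MIN_TRANSCRIPT_BP,
) -> GenomicInterval | None:
    """Strand-aware body interval from TSS+offset to the gene end, or
    None for transcripts at or below the minimum length (or shorter than
    the offset itself)."""
    if offset_bp < 0 or min_len_bp < 0:
        raise ValueError("offsets must be non-negative")
    if t.length <= min_len_bp or offset_bp >= t.length:
        return None
    iv = t.interval
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, iv.start + offset_bp, iv.end, "+")
    return GenomicInterval(iv.chrom, iv.start, iv.end - offset_bp, "-")


def transcript_densities(
    transcripts: list[Transcript],
    track: StrandedReadTrack,
    mapability: MapabilityTrack,
    offset_bp: int = DEFAULT_BODY_OFFSET_BP,
    min_len_bp: int = DEFAULT_MIN_TRANSCRIPT_BP,
) -> dict[str, DensityValue]:
    """Sense-strand body density per transcript accession.  Transcripts
    without a body (too short) are omitted."""
    out: dict[str, DensityValue] = {}
    for t in transcripts:
        body = transcript_body(t, offset_bp, min_len_bp)
        if body is None:
            continue
        out[t.accession] = window_density(track, body, "sense", mapability)
    return out


@dataclass
class RocResult:
    """Maximal-accuracy cutoff with the full ROC curve behind it."""

    cutoff: float
    accuracy: float
    sensitivity: float
    specificity: float
    #: (cutoff, TPR, FPR, accuracy) per candidate threshold, ascending cutoff
    curve: list[tuple[float, float, float, float]]


def maximal_accuracy_cutoff(
    densities: dict[str, float], labels: dict[str, str]
) -> RocResult:
    """Choose the density cutoff maximizing (TP + TN) / total.

    Candidate thresholds are every observed density value plus one value
    above the maximum (so that the all-negative rule is a candidate).
    Ties in accuracy go to the smallest cutoff.
    """
    pos = [float(densities[k]) for k, v in labels.items() if v == "expressed"]
    neg = [float(densities[k]) for k, v in labels.items() if v == "non-expressed"]
    if not pos or not neg:
        raise ValueError("both label classes must be non-empty")
    pos_a = np.sort(np.array(pos))
    neg_a = np.sort(np.array(neg))
    n_pos, n_neg = len(pos_a), len(neg_a)
    observed = np.unique(np.concatenate([pos_a, neg_a]))
    candidates = np.concatenate([observed, [observed[-1] + 1.0]])

    curve: list[tuple[float, float, float, float]] = []
    best: tuple[float, float, float, float] | None = None
    for c in candidates:
        tp = n_pos - int(np.searchsorted(pos_a, c, "left"))  # density >= c
        fp = n_neg - int(np.searchsorted(neg_a, c, "left"))
        tpr = tp / n_pos
        fpr = fp / n_neg
        acc = (tp + (n_neg - fp)) / (n_pos + n_neg)
        curve.append((float(c), tpr, fpr, acc))
        if best is None or acc > best[1]:
            best = (float(c), acc, tpr, 1.0 - fpr)
    return RocResult(
        cutoff=best[0],
        accuracy=best[1],
        sensitivity=best[2],
        specificity=best[3],
        curve=curve,
    )


def call_active_transcripts(
    densities: dict[str, DensityValue | float],
    cutoff: float,
    transcripts: list[Transcript] | None = None,
) -> tuple[set[str], set[str]]:
    """Accessions with defined density >= cutoff, plus the subset after
    collapsing to unique gene symbols (longest transcript per symbol)."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    active: set[str] = set()
    for acc, d in densities.items():
        if isinstance(d, DensityValue):
            if not d.defined:
                continue
            d = d.value
        if d >= cutoff:
            active.add(acc)
    if transcripts is None:
        return active, set(active)
    by_symbol: dict[str, Transcript] = {}
    for t in transcripts:
        if t.accession not in active:
            continue
        cur = by_symbol.get(t.gene_symbol)
        if cur is None or (t.length, t.accession) > (cur.length, cur.accession):
            by_symbol[t.gene_symbol] = t
    return active, {t.accession for t in by_symbol.values()}


def write_roc_curve(roc: RocResult, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("cutoff\ttpr\tfpr\taccuracy\n")
        for c, tpr, fpr, acc in roc.curve:
            fh.write(f"{c:.6g}\t{tpr:.6f}\t{fpr:.6f}\t{acc:.6f}\n")


def write_activity_report(
    densities: dict[str, DensityValue], active: set[str], path: str
) -> None:
    with open(path, "w") as fh:
        fh.write("transcript\tdensity\tactive\n")
        for acc in sorted(densities):
            d = densities[acc]
            dtxt = f"{d.value:.6g}" if d.defined else "NA"
            fh.write(f"{acc}\t{dtxt}\t{int(acc in active)}\n")
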