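"""Genomic file formats and shared coordinate conventions.

Every coordinate in this package is 0-based, half-open: an interval
``[start, end)`` covers ``end - start`` bases.  Strands are ``"+"``,
``"-"`` or ``"."`` (unstranded).  Supported formats are plain-text,
tab-separated: refFlat-like transcript tables, BED3/BED5/BED6/BED12,
per-strand bedGraph read tracks, and fixedStep/variableStep wiggle or
BED4 mapability tracks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

#: How a read is reduced to a single anchor position.
#: "five_prime": the 5' end on the read's own strand (start for +, end-1 for -).
#: "midpoint": the integer midpoint of the read interval.
ANCHOR_CONVENTIONS = ("five_prime", "midpoint")


class ParseError(ValueError):
    """Raised for malformed input records; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Transcript:
    """An annotated transcript with strand-aware TSS and gene end.

    ``tss`` is the base at which transcription starts (interval start on
    the plus strand, ``end - 1`` on the minus strand); ``gene_end`` is
    the opposite terminus.  ``is_validated_mrna`` records whether the
    accession carries the validated-mRNA prefix (``NM_`` for RefSeq).
    """

    accession: str
    gene_symbol: str
    interval: GenomicInterval
    is_validated_mrna: bool

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.accession} must be stranded")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def gene_end(self) -> int:
        iv = self.interval
        return iv.end - 1 if iv.strand == "+" else iv.start

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass
class PeakSet:
    """A named collection of unstranded peaks, kept sorted by (chrom, start)."""

    name: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


class StrandedReadTrack:
    """Per-chromosome sorted arrays of read anchor positions, one per strand.

    The anchor is a single base position per read; windowed counts are
    computed with binary search, so lookups are O(log n).
    """

    def __init__(self, anchors: dict[str, dict[str, np.ndarray]] | None = None):
        # anchors[chrom][strand] -> sorted int64 array
        self._anchors: dict[str, dict[str, np.ndarray]] = {}
        if anchors:
            for chrom, per_strand in anchors.items():
                for strand, pos in per_strand.items():
                    self._set(chrom, strand, np.asarray(pos, dtype=np.int64))

    def _set(self, chrom: str, strand: str, pos: np.ndarray) -> None:
        if strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {strand!r}")
        if pos.size and pos.min() < 0:
            raise ValueError("negative read coordinate")
        self._anchors.setdefault(chrom, {})[strand] = np.sort(pos)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._anchors)

    def positions(self, chrom: str, strand: str) -> np.ndarray:
        return self._anchors.get(chrom, {}).get(strand, np.empty(0, dtype=np.int64))

    def count(self, chrom: str, start: int, end: int, strand: str) -> int:
        pos = self.positions(chrom, strand)
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))

    def total(self, strand: str) -> int:
        return sum(self.positions(c, strand).size for c in self._anchors)

    def scaled(self, factor: int) -> "StrandedReadTrack":
        """A track with every anchor repeated ``factor`` times (for scaling tests)."""
        out = {}
        for chrom, per_strand in self._anchors.items():
            out[chrom] = {s: np.repeat(p, factor) for s, p in per_strand.items()}
        return StrandedReadTrack(out)


class MapabilityTrack:
    """Piecewise-constant per-base alignability values in [0, 1].

    Positions not covered by any interval take ``default`` (0.0 unless
    configured otherwise — conservative, since unalignable sequence
    contributes no reads).
    """

    def __init__(self, default: float = 0.0):
        if not 0.0 <= default <= 1.0:
            raise ValueError("default mapability must be in [0, 1]")
        self.default = default
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self._pending: dict[str, list[tuple[int, int, float]]] = {}

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"mapability value {value} outside [0, 1]")
        if end <= start or start < 0:
            raise ValueError(f"bad mapability interval [{start}, {end})")
        self._pending.setdefault(chrom, []).append((start, end, value))
        self._starts.pop(chrom, None)

    def _ensure(self, chrom: str) -> None:
        if chrom in self._starts or chrom not in self._pending:
            if chrom not in self._starts:
                self._starts[chrom] = np.empty(0, dtype=np.int64)
                self._ends[chrom] = np.empty(0, dtype=np.int64)
                self._values[chrom] = np.empty(0)
            return
        ivs = sorted(self._pending[chrom])
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping mapability intervals on {chrom}")
        self._starts[chrom] = np.array([s for s, _, _ in ivs], dtype=np.int64)
        self._ends[chrom] = np.array([e for _, e, _ in ivs], dtype=np.int64)
        self._values[chrom] = np.array([v for _, _, v in ivs])

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean mapability over [start, end)."""
        if end <= start:
            raise ValueError("empty window")
        self._ensure(chrom)
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        lo = np.searchsorted(ends, start, "right")
        hi = np.searchsorted(starts, end, "left")
        total = 0.0
        covered = 0
        for i in range(lo, hi):
            ov = min(int(ends[i]), end) - max(int(starts[i]), start)
            if ov > 0:
                total += ov * float(values[i])
                covered += ov
        total += (end - start - covered) * self.default
        return total / (end - start)

    @classmethod
    def uniform(cls, value: float = 1.0) -> "MapabilityTrack":
        """A track that reports ``value`` everywhere."""
        return cls(default=value)


@dataclass(frozen=True)
class WindowPrediction:
    """A scanned 2-kb window: assigned class, posterior vector, LOD score."""

    window: GenomicInterval
    label: str  # "B", "E" or "N"
    posteriors: tuple[float, float, float]  # (B, E, N)
    lod: float
    high_confidence: bool


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _fields(line: str, lineno: int, minimum: int, path: str) -> list[str]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) < minimum:
        raise ParseError(f"{path}:{lineno}: expected >= {minimum} fields, got {len(parts)}")
    return parts


def read_transcripts(path: str, validated_prefix: str = "NM_") -> list[Transcript]:
    """Read a refFlat-like TSV or BED12 transcript table.

    refFlat-like columns: accession, gene symbol, chrom, strand, txStart,
    txEnd.  BED12 (or BED6) columns: chrom, start, end, name, score,
    strand.  The two layouts are distinguished per line by whether
    columns 2-3 parse as integers.
    """
    if not validated_prefix:
        raise ValueError("validated_prefix must be non-empty")
    out: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _fields(line, lineno, 6, path)
            try:
                if parts[1].lstrip("-").isdigit() and parts[2].lstrip("-").isdigit():
                    # BED layout
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    accession, strand = parts[3], parts[5]
                    symbol = accession
                else:
                    accession, symbol, chrom, strand = parts[0], parts[1], parts[2], parts[3]
                    start, end = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                iv = GenomicInterval(chrom, start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(
                Transcript(
                    accession=accession,
                    gene_symbol=symbol,
                    interval=iv,
                    is_validated_mrna=accession.startswith(validated_prefix),
                )
            )
    return out


def _read_anchor(start: int, end: int, strand: str, convention: str) -> int:
    if convention == "five_prime":
        return start if strand == "+" else end - 1
    if convention == "midpoint":
        return (start + end) // 2
    raise ValueError(f"unknown anchor convention {convention!r}")


def _load_read_file(path: str, designated: str, convention: str) -> dict[str, list[int]]:
    """One strand's reads from BED6 (one read per row) or bedGraph (counts)."""
    per_chrom: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected BED6 or bedGraph row")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start < 0:
                raise ParseError(f"{path}:{lineno}: negative coordinate")
            if len(parts) >= 6 and parts[5] in ("+", "-"):
                strand = parts[5]
                if strand != designated:
                    warnings.warn(
                        f"{path}:{lineno}: read strand {strand} disagrees with the "
                        f"file's designated strand {designated}; keeping the strand column",
                        stacklevel=2,
                    )
                anchor = _read_anchor(start, end, strand, convention)
                per_chrom.setdefault(strand + chrom, []).append(anchor)
            else:
                # bedGraph: column 4 is a read count at this span's start
                try:
                    count = int(round(float(parts[3])))
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                per_chrom.setdefault(designated + chrom, []).extend([start] * count)
    return per_chrom


def read_stranded_reads(
    path_plus: str, path_minus: str, anchor: str = "five_prime"
) -> StrandedReadTrack:
    """Build a :class:`StrandedReadTrack` from per-strand BED6/bedGraph files.

    BED6 rows whose strand column disagrees with the file's designated
    strand are reassigned to the strand column (with a warning).
    """
    merged: dict[str, dict[str, list[int]]] = {}
    for path, designated in ((path_plus, "+"), (path_minus, "-")):
        for key, positions in _load_read_file(path, designated, anchor).items():
            strand, chrom = key[0], key[1:]
            merged.setdefault(chrom, {}).setdefault(strand, []).extend(positions)
    return StrandedReadTrack(
        {c: {s: np.array(p, dtype=np.int64) for s, p in d.items()} for c, d in merged.items()}
    )


def read_peaks(path: str, name: str | None = None) -> PeakSet:
    """Read a BED3/BED5/BED6 peak file into an unstranded :class:`PeakSet`."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = _fields(line, lineno, 3, path)
            try:
                peaks.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(name=name or path, peaks=peaks)


def read_mapability(path: str, default: float = 0.0) -> MapabilityTrack:
    """Read a mapability track from BED4 or fixedStep/variableStep wiggle."""
    track = MapabilityTrack(default=default)
    chrom = None
    step = span = 1
    pos = 0
    mode = "bed"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wiggle declarations are 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                mode = "fixed"
                continue
            if line.startswith("variableStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                mode = "variable"
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                if mode == "fixed":
                    track.add(chrom, pos, pos + span, float(parts[0]))
                    pos += step
                elif mode == "variable":
                    p = int(parts[0]) - 1
                    track.add(chrom, p, p + span, float(parts[1]))
                else:
                    track.add(parts[0], int(parts[1]), int(parts[2]), float(parts[3]))
            except (ValueError, IndexError, TypeError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return track


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column chrom-sizes table (name, length in bp)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = _fields(line, lineno, 2, path)
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_expression_labels(path: str) -> dict[str, str]:
    """Read a two-column TSV mapping transcript accession to an
    'expressed' / 'non-expressed' truth label."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _fields(line, lineno, 2, path)
            if parts[1] not in ("expressed", "non-expressed"):
                raise ParseError(f"{path}:{lineno}: unknown label {parts[1]!r}")
            labels[parts[0]] = parts[1]
    return labels


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_predictions(
    predictions: Sequence[WindowPrediction], path: str, precision: int = 4
) -> None:
    """Write predictions as BED6+3 (class in the name column, LOD as the
    score, then the three posterior probabilities), sorted by
    (chrom, start, strand)."""
    rows = sorted(predictions, key=lambda p: (p.window.chrom, p.window.start, p.window.strand))
    with open(path, "w") as fh:
        for p in rows:
            if not np.isfinite(p.lod):
                raise ValueError(f"non-finite LOD for {p.window}")
            w = p.window
            post = "\t".join(f"{q:.{precision}f}" for q in p.posteriors)
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{p.label}\t"
                f"{p.lod:.{precision}f}\t{w.strand}\t{post}\n"
            )


def read_predictions(path: str, lod_threshold: float = 2.5) -> list[WindowPrediction]:
    """Read back a predictions BED6+3 file written by :func:`write_predictions`."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = _fields(line, lineno, 9, path)
            lod = float(parts[4])
            out.append(
                WindowPrediction(
                    window=GenomicInterval(parts[0], int(parts[1]), int(parts[2]), parts[5]),
                    label=parts[3],
                    posteriors=(float(parts[6]), float(parts[7]), float(parts[8])),
                    lod=lod,
                    high_confidence=lod > lod_threshold,
                )
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str, name: str = ".") -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda v: (v.chrom, v.start, v.end)):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
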