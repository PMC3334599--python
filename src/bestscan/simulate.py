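"""Seeded synthetic GRO-seq datasets with known ground truth.

The generator emulates the read-level structure that nascent-
transcription methods rely on, at the density level (independent
Poisson-placed read anchors, no fragments or sequence content):

* promoter pause signature at expressed-gene TSSs — a sense-strand
  read spike just downstream of the TSS plus a divergent antisense
  spike immediately upstream (the BEST signature);
* uniform lower-density sense-strand elongation over expressed gene
  bodies, with per-gene expression rates spanning an order of
  magnitude;
* sparse uniform background noise on both strands;
* planted intergenic BEST loci with the same bidirectional spike
  shape, kept well clear of the promoter/gene-end exclusion zones so
  they fall inside the classifier's search space;
* peak files (DHS-like, H3K27ac-like, CTCF-like) placed over planted
  loci at a controlled rate q and at random background positions, plus
  H3K4me3-like peaks at expressed promoters;
* a piecewise-constant mapability track with a configurable fraction
  of reduced-mapability segments.

Everything is written in the package's plain-text formats and is
byte-reproducible from the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .classifier import IntervalMask
from .io import GenomicInterval, PeakSet, StrandedReadTrack, WindowPrediction


@dataclass
class MarkSpec:
    """One synthetic peak set: placement rate over planted loci, number of
    random background peaks, and the peak width range."""

    q_truth: float = 0.8
    n_background: int = 300
    width_min: int = 200
    width_max: int = 600


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Rates are chosen to resemble a deeply sequenced GRO-seq library in a
    mammalian cell line: tens of reads in the promoter pause peak,
    body elongation densities of a few to a few tens of reads/kb for
    expressed genes, and near-silent background.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_genes: int = 200
    gene_len_min: int = 4_000
    gene_len_max: int = 20_000
    gene_spacing_bp: int = 16_000  # min gap between genes
    frac_expressed: float = 0.8
    frac_unvalidated: float = 0.05  # NR_-style accessions, kept silent
    elongation_rate_min: float = 5.0  # reads/kb, expressed genes (log-uniform)
    elongation_rate_max: float = 50.0
    silent_rate: float = 0.2  # reads/kb, non-expressed gene bodies
    expression_split: float = 2.5  # true-rate threshold for the label file
    sense_spike_mean: float = 60.0  # Poisson mean, TSS..TSS+150 (sense)
    antisense_spike_mean: float = 40.0  # Poisson mean, TSS-250..TSS (antisense)
    spike_len: int = 150
    antisense_spike_len: int = 250
    n_planted_best: int = 50
    planted_spike_scale: float = 1.0
    planted_clearance_bp: int = 15_000  # min distance to genes and other loci
    noise_rate: float = 0.1  # reads/kb per strand, genome-wide
    low_map_fraction: float = 0.02
    low_map_value_min: float = 0.3
    low_map_value_max: float = 0.8
    low_map_seg_min: int = 500
    low_map_seg_max: int = 2000
    marks: dict[str, MarkSpec] = field(
        default_factory=lambda: {
            "dhs": MarkSpec(q_truth=0.8, n_background=300),
            "h3k27ac": MarkSpec(q_truth=0.6, n_background=200),
            "ctcf": MarkSpec(q_truth=0.2, n_background=300),
        }
    )

    def to_json(self, path: str) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str) -> "SyntheticConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "marks" in d:
            d["marks"] = {k: MarkSpec(**v) for k, v in d["marks"].items()}
        return cls(**d)


@dataclass
class SyntheticGene:
    accession: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    rate: float  # true elongation rate, reads/kb
    expressed: bool
    validated: bool

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class SyntheticDataset:
    """File paths plus in-memory ground truth for one generated dataset."""

    outdir: str
    genes_path: str
    reads_plus_path: str
    reads_minus_path: str
    mapability_path: str
    chrom_sizes_path: str
    labels_path: str
    truth_path: str
    peak_paths: dict[str, str]
    genes: list[SyntheticGene]
    truth: list[GenomicInterval]  # planted BEST spike footprints
    chrom_sizes: dict[str, int]


# ---------------------------------------------------------------------------
# Placement helpers
# ---------------------------------------------------------------------------

def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    lengths: list[int],
    occupied: dict[str, list[tuple[int, int]]],
    margin: int,
    max_tries: int = 500,
) -> list[GenomicInterval]:
    """Place intervals of the given lengths, each at least ``margin`` bp
    from everything already in ``occupied`` (which is updated in place)."""
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    out: list[GenomicInterval] = []
    for i, length in enumerate(lengths):
        for _ in range(max_tries):
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            limit = chrom_sizes[chrom] - length - margin
            if limit <= margin:
                continue
            start = int(rng.integers(margin, limit))
            end = start + length
            clash = any(
                s - margin < end and start < e + margin
                for s, e in occupied.get(chrom, [])
            )
            if not clash:
                occupied.setdefault(chrom, []).append((start, end))
                out.append(GenomicInterval(chrom, start, end))
                break
        else:
            raise RuntimeError(
                f"could not place region {i + 1}/{len(lengths)}: genome too crowded"
            )
    return out


def _poisson_positions(
    rng: np.random.Generator, start: int, end: int, mean_count: float
) -> np.ndarray:
    """Poisson(mean_count) read anchors placed uniformly in [start, end)."""
    n = rng.poisson(mean_count)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    return rng.integers(start, end, size=n).astype(np.int64)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate(config: SyntheticConfig, outdir: str) -> SyntheticDataset:
    """Generate a complete dataset and write it under ``outdir``.

    The same configuration always produces byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    os.makedirs(outdir, exist_ok=True)
    sizes = dict(config.chrom_sizes)

    # --- genes ----------------------------------------------------------
    lengths = [
        int(rng.integers(config.gene_len_min, config.gene_len_max + 1))
        for _ in range(config.n_genes)
    ]
    occupied: dict[str, list[tuple[int, int]]] = {}
    gene_ivs = _place_nonoverlapping(
        rng, sizes, lengths, occupied, margin=config.gene_spacing_bp
    )
    genes: list[SyntheticGene] = []
    for i, iv in enumerate(gene_ivs):
        validated = rng.random() >= config.frac_unvalidated
        expressed = validated and (rng.random() < config.frac_expressed)
        if expressed:
            lo, hi = np.log(config.elongation_rate_min), np.log(config.elongation_rate_max)
            rate = float(np.exp(rng.uniform(lo, hi)))
        else:
            rate = config.silent_rate
        strand = "+" if rng.random() < 0.5 else "-"
        prefix = "NM_" if validated else "NR_"
        genes.append(
            SyntheticGene(
                accession=f"{prefix}{i:05d}",
                symbol=f"GENE{i:04d}",
                chrom=iv.chrom,
                start=iv.start,
                end=iv.end,
                strand=strand,
                rate=rate,
                expressed=expressed,
                validated=validated,
            )
        )

    # --- planted intergenic BEST loci -----------------------------------
    # kept planted_clearance_bp away from genes so that neither the locus
    # window nor its flanking windows hit the promoter/gene-end exclusion
    truth = _place_nonoverlapping(
        rng,
        sizes,
        [config.antisense_spike_len + config.spike_len] * config.n_planted_best,
        occupied,
        margin=config.planted_clearance_bp,
    )
    planted_strands = ["+" if rng.random() < 0.5 else "-" for _ in truth]

    # --- reads ----------------------------------------------------------
    reads: dict[str, dict[str, list[np.ndarray]]] = {
        c: {"+": [], "-": []} for c in sizes
    }
    for chrom, size in sorted(sizes.items()):
        for strand in ("+", "-"):
            reads[chrom][strand].append(
                _poisson_positions(rng, 0, size, config.noise_rate * size / 1000.0)
            )
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        if not g.expressed:
            if g.validated:
                body_mean = g.rate * (g.end - g.start) / 1000.0
                strand = g.strand
                reads[g.chrom][strand].append(
                    _poisson_positions(rng, g.start, g.end, body_mean)
                )
            continue
        strand = g.strand
        anti = "-" if strand == "+" else "+"
        body_mean = g.rate * (g.end - g.start) / 1000.0
        reads[g.chrom][strand].append(_poisson_positions(rng, g.start, g.end, body_mean))
        # pause spike: sense just downstream of the TSS, antisense upstream
        if strand == "+":
            s_lo, s_hi = g.tss, g.tss + config.spike_len
            a_lo, a_hi = g.tss - config.antisense_spike_len, g.tss
        else:
            s_lo, s_hi = g.tss - config.spike_len + 1, g.tss + 1
            a_lo, a_hi = g.tss + 1, g.tss + 1 + config.antisense_spike_len
        reads[g.chrom][strand].append(
            _poisson_positions(rng, s_lo, s_hi, config.sense_spike_mean)
        )
        reads[g.chrom][anti].append(
            _poisson_positions(rng, a_lo, a_hi, config.antisense_spike_mean)
        )
    for iv, strand in zip(truth, planted_strands):
        anti = "-" if strand == "+" else "+"
        scale = config.planted_spike_scale
        if strand == "+":
            a_lo = iv.start
            a_hi = iv.start + config.antisense_spike_len
            s_lo, s_hi = a_hi, a_hi + config.spike_len
        else:
            s_lo = iv.start
            s_hi = iv.start + config.spike_len
            a_lo, a_hi = s_hi, s_hi + config.antisense_spike_len
        reads[iv.chrom][strand].append(
            _poisson_positions(rng, s_lo, s_hi, config.sense_spike_mean * scale)
        )
        reads[iv.chrom][anti].append(
            _poisson_positions(rng, a_lo, a_hi, config.antisense_spike_mean * scale)
        )

    anchors = {
        c: {s: np.sort(np.concatenate(parts)) if parts else np.empty(0, dtype=np.int64)
            for s, parts in per.items()}
        for c, per in reads.items()
    }

    # --- mapability ------------------------------------------------------
    map_segments: dict[str, list[tuple[int, int, float]]] = {c: [] for c in sizes}
    for chrom, size in sorted(sizes.items()):
        target_low = config.low_map_fraction * size
        low_total = 0
        cursor = 0
        segs: list[tuple[int, int, float]] = []
        while low_total < target_low:
            seg_len = int(rng.integers(config.low_map_seg_min, config.low_map_seg_max + 1))
            pos = int(rng.integers(0, size - seg_len))
            if any(s < pos + seg_len and pos < e for s, e, _ in segs):
                continue
            value = float(
                np.round(rng.uniform(config.low_map_value_min, config.low_map_value_max), 3)
            )
            segs.append((pos, pos + seg_len, value))
            low_total += seg_len
        map_segments[chrom] = sorted(segs)

    # --- peaks ----------------------------------------------------------
    peak_sets: dict[str, PeakSet] = {}
    for mark_name in sorted(config.marks):
        spec = config.marks[mark_name]
        peaks: list[GenomicInterval] = []
        for iv in truth:
            if rng.random() < spec.q_truth:
                width = int(rng.integers(spec.width_min, spec.width_max + 1))
                center = iv.midpoint
                start = max(0, center - width // 2)
                peaks.append(GenomicInterval(iv.chrom, start, start + width))
        chroms = sorted(sizes)
        weights = np.array([sizes[c] for c in chroms], dtype=float)
        weights /= weights.sum()
        for _ in range(spec.n_background):
            width = int(rng.integers(spec.width_min, spec.width_max + 1))
            chrom = chroms[int(rng.choice(len(chroms), p=weights))]
            start = int(rng.integers(0, sizes[chrom] - width))
            peaks.append(GenomicInterval(chrom, start, start + width))
        peak_sets[mark_name] = PeakSet(name=mark_name, peaks=peaks)
    # H3K4me3 at expressed promoters (the promoter mark used for exclusion)
    k4_peaks = [
        GenomicInterval(g.chrom, max(0, g.tss - 500), g.tss + 500)
        for g in genes
        if g.expressed
    ]
    peak_sets["h3k4me3"] = PeakSet(name="h3k4me3", peaks=k4_peaks)

    # --- write everything ------------------------------------------------
    paths = {
        "genes": os.path.join(outdir, "genes.refflat.tsv"),
        "reads_plus": os.path.join(outdir, "reads_plus.bedgraph"),
        "reads_minus": os.path.join(outdir, "reads_minus.bedgraph"),
        "mapability": os.path.join(outdir, "mapability.bed4"),
        "chrom_sizes": os.path.join(outdir, "chrom.sizes"),
        "labels": os.path.join(outdir, "expression_labels.tsv"),
        "truth": os.path.join(outdir, "truth_best_loci.bed"),
        "config": os.path.join(outdir, "config.json"),
    }
    config.to_json(paths["config"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")
    with open(paths["genes"], "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.accession}\t{g.symbol}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\n"
            )
    for strand, key in (("+", "reads_plus"), ("-", "reads_minus")):
        with open(paths[key], "w") as fh:
            for chrom in sorted(anchors):
                pos = anchors[chrom][strand]
                if pos.size == 0:
                    continue
                uniq, counts = np.unique(pos, return_counts=True)
                for p, c in zip(uniq.tolist(), counts.tolist()):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t{c}\n")
    with open(paths["mapability"], "w") as fh:
        for chrom in sorted(sizes):
            cursor = 0
            for s, e, v in map_segments[chrom]:
                if s > cursor:
                    fh.write(f"{chrom}\t{cursor}\t{s}\t1\n")
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
                cursor = e
            if cursor < sizes[chrom]:
                fh.write(f"{chrom}\t{cursor}\t{sizes[chrom]}\t1\n")
    with open(paths["labels"], "w") as fh:
        for g in sorted(genes, key=lambda g: g.accession):
            if not g.validated:
                continue
            label = "expressed" if g.rate >= config.expression_split else "non-expressed"
            fh.write(f"{g.accession}\t{label}\n")
    with open(paths["truth"], "w") as fh:
        for iv, strand in sorted(
            zip(truth, planted_strands), key=lambda x: (x[0].chrom, x[0].start)
        ):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tbest\t0\t{strand}\n")
    peak_paths: dict[str, str] = {}
    for name, ps in sorted(peak_sets.items()):
        p = os.path.join(outdir, f"peaks_{name}.bed")
        with open(p, "w") as fh:
            for pk in ps:
                fh.write(f"{pk.chrom}\t{pk.start}\t{pk.end}\n")
        peak_paths[name] = p

    return SyntheticDataset(
        outdir=outdir,
        genes_path=paths["genes"],
        reads_plus_path=paths["reads_plus"],
        reads_minus_path=paths["reads_minus"],
        mapability_path=paths["mapability"],
        chrom_sizes_path=paths["chrom_sizes"],
        labels_path=paths["labels"],
        truth_path=paths["truth"],
        peak_paths=peak_paths,
        genes=genes,
        truth=truth,
        chrom_sizes=sizes,
    )


# ---------------------------------------------------------------------------
# Truth evaluation and controlled peak planting
# ---------------------------------------------------------------------------

def truth_overlap_report(
    predictions: list[WindowPrediction], truth: list[GenomicInterval]
) -> tuple[float, float]:
    """(sensitivity, precision) of high-confidence predictions against
    the planted loci: a truth locus is recovered when at least one
    high-confidence window intersects it; a prediction is correct when
    it intersects at least one truth locus."""
    if not truth:
        raise ValueError("empty truth set: sensitivity undefined")
    hc = [p.window for p in predictions if p.high_confidence]
    recovered = sum(1 for t in truth if any(t.overlaps(w) for w in hc))
    sensitivity = recovered / len(truth)
    if not hc:
        return sensitivity, float("nan")
    correct = sum(1 for w in hc if any(w.overlaps(t) for t in truth))
    return sensitivity, correct / len(hc)


def plant_peaks_over_windows(
    truth_windows: list[GenomicInterval],
    background_windows: list[GenomicInterval],
    q: float,
    r: float,
    seed: int,
    width: int = 300,
) -> PeakSet:
    """Bernoulli peak placement used for enrichment calibration: a peak is
    centered inside each truth window with probability ``q`` and inside
    each background window with probability ``r``."""
    rng = np.random.default_rng(seed)
    peaks: list[GenomicInterval] = []
    for windows, rate in ((truth_windows, q), (background_windows, r)):
        for w in windows:
            if rng.random() < rate:
                center = w.midpoint
                start = max(0, center - width // 2)
                peaks.append(GenomicInterval(w.chrom, start, start + width))
    return PeakSet(name=f"planted_q{q}_r{r}", peaks=peaks)
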