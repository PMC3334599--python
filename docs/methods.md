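# Methods

## Coordinates and read anchors

All coordinates are 0-based, half-open. A transcript's TSS is its
interval start on the plus strand and `end − 1` on the minus strand;
the gene end is the opposite terminus. Each read is reduced to a single
anchor position — by default its 5′ end on its own strand, because
nascent-transcription density is a polymerase-position signal; a
midpoint convention is available. An anchor contributes to exactly one
window or bin, so counts are exactly additive over any partition of a
region.

## Read density and mapability

The core statistic is reads/kb/mapability: the anchor count in a
window, divided by the window length in kb, divided by the window's
length-weighted mean mapability. Bases not covered by the mapability
track default to mapability 0 (conservative: unalignable sequence
contributes no reads, so treating it as alignable would deflate
densities). Windows whose mean mapability is at or below a floor
(default 0.05) yield an *undefined* density instead of an enormous one;
undefined windows are excluded from training, scanning and profiling
rather than raising errors mid-pipeline.

## Active-gene calling

Transcript activity is the sense-strand density over the transcript
body, defined as TSS + 1 kb to the annotated gene end; transcripts of
3 kb or less carry no body (the promoter pause peak would dominate).
The activity cutoff is chosen by maximal accuracy,
(TP + TN) / total, against a labeled expressed/non-expressed gene set.
Candidate thresholds are every observed density value plus one value
above the maximum (the all-negative rule), making the search exhaustive
and finite; the call rule is boundary-inclusive (density ≥ cutoff), and
accuracy ties go to the smallest cutoff. When collapsing transcripts to
unique gene symbols the longest transcript per symbol is kept.

## The three-class model

Training windows are 2 kb, centered on active TSSs (class B), active
transcript midpoints (class E), and midpoints of seeded random
intergenic regions (class N) that are length-matched to the active
transcripts and overlap no known transcript. Intergenic windows get
random strands, since background is strand-symmetric.

The six features are strand-relative: sense and antisense density in
the window, and the four ratios of those densities to the neighboring
2-kb windows 3′ and 5′ of it (on a minus-strand window, 3′ is the
lower-coordinate side). Ratios are regularized with a symmetric
pseudocount (default 0.1 reads/kb/mapability) added to numerator and
denominator; at pseudocount 0, a 0/0 ratio counts as equality (1.0) and
a finite/0 ratio marks the window unusable. This keeps every feature
finite and makes f3–f6 exactly invariant under uniform scaling of all
read counts.

Class-conditional distributions are histograms over quantile bins
(default 20) computed on the pooled all-class log1p-transformed values
per feature, so all classes share one grid per feature; duplicated
quantiles collapse, shrinking the effective bin count. Bin masses get
Laplace smoothing, (count + α) / (n + kα) with α = 1 by default, which
guarantees strictly positive masses and therefore finite
log-likelihoods everywhere. Priors are equal (1/3). A feature value
outside the grid clamps to the nearest edge bin. Scoring is done in log
space; with equal priors, class B is assigned exactly when LOD > 0.
Exact ties at the argmax resolve in the order N, then E, then B —
biased against false BEST calls. Models serialize to versioned JSON
(priors, bin edges, masses, transform, pseudocounts).

## Genome scan

Each chromosome is tiled with non-overlapping 2-kb windows from
coordinate 0 (no offset sweep). A window is dropped when it or either
flanking 2-kb window intersects the exclusion mask — the union of 7-kb
neighborhoods around every TSS, annotated gene end, and H3K4me3 peak —
falls off the chromosome, or has undefined density. Surviving windows
are evaluated on both strands; one prediction per genomic window is
emitted carrying the max-LOD strand, and it is a high-confidence BEST
locus when LOD exceeds the threshold (default 2.5, strict inequality)
on either strand. Adjacent high-confidence windows are not merged.

## Enrichment statistics

Background windows are drawn uniformly (seeded) from the same
non-promoter search space, rejecting any draw that touches the
exclusion mask or extra excluded peak sets; the background count
defaults to the observation count. A window "overlaps" a peak at ≥ 1 bp
of shared sequence (half-open, so abutting intervals do not overlap).
Fold enrichment is the observed over the background overlap frequency;
significance is the two-tailed Pearson chi-squared test on the 2×2
counts, df = 1, without Yates correction (the intended regime is
large counts). Chromatin-mark representation uses pooled reads/bp
(total reads over total bp across regions, both strands) and reports
ln[(treat@loci / treat@bg) / (input@loci / input@bg)]; per-replicate
values and their SD are reported when replicates are supplied.

## Proportional-distance profiles

For a peak of length L with 5-kb flanks and 150-bp bins, upstream bins
tile backwards from the peak start, interior bins forward from the
start, and downstream bins forward from the peak end; partial bins keep
their own lengths and normalization. The proportional coordinate of
genomic position x is (x − start) / L, so the interior spans [0, 1] and
a 300-bp peak has boundaries −0.5, 0, 0.5, 1, 1.5 around its edges.
Per region and strand, relative density is bin density divided by the
region's mean density, where the mean is the length-weighted mean of
the bin densities themselves — this makes the per-region normalization
identity (length-weighted mean of relative density = 1) hold exactly,
even under non-uniform mapability. Regions are aggregated by
proportional-overlap-weighted resampling onto a fixed grid (bins of
width 0.1 over [−2, 3]); grid bins beyond a region's proportional
extent receive no contribution from it, so short peaks inform wide
proportional flanks and long peaks narrow ones. Regions with an
undefined bin or zero density on either strand are skipped and counted.
Unstranded peaks use plus-strand reads as "sense/plus". The gene
metaprofile is the strand-aware analogue: TSS ↦ 0, gene end ↦ 1,
flanks of half a gene length, normalized per transcript per strand.

## Pausing index

Index = sense density in [TSS, TSS + 1 kb) divided by sense density in
the body (TSS + 1 kb to the gene end), strand-aware. The exact window
sizes are a package choice and configurable; the scientifically
testable property is the inverse rank correlation between the index
and body expression, which the tests check on a simulated cohort. Zero
body density flags the index undefined.

## Synthetic data

The generator emulates, at the density level, the structures the
method consumes: Poisson-placed independent read anchors forming (i) a
promoter pause signature at expressed TSSs — Poisson-mean 60 sense
reads in [TSS, TSS+150) and 40 antisense reads in [TSS−250, TSS) —
(ii) uniform sense elongation over gene bodies with per-gene rates
log-uniform on 5–50 reads/kb (silent genes 0.2 reads/kb), (iii) sparse
background noise at 0.1 reads/kb per strand, (iv) 50 planted intergenic
loci carrying the same bidirectional spike, and (v) peak sets placed
over planted loci with probability q (DHS-like 0.8, H3K27ac-like 0.6,
CTCF-like 0.2) plus random background peaks, and H3K4me3-like peaks at
expressed promoters. The default genome is two 5-Mb chromosomes with
200 non-overlapping genes of 4–20 kb; these sizes keep a full
train-and-scan cycle in the order of seconds while leaving ~1,700
scannable non-promoter windows, enough for stable recovery statistics.
Planted loci are kept 15 kb clear of gene TSSs/ends so that neither
the locus window nor its feature flanks touch the 7-kb exclusion mask.
Mapability is piecewise-constant, mostly 1.0 with ~2% of the genome in
segments of 0.3–0.8 to exercise the normalization (values stay above
the floor; the undefined-density path is exercised separately in unit
tests). Generation is byte-reproducible from the configuration.

What the generator does *not* model — fragment structure, sequence
content, PCR/nucleotide bias, duplicated reads, spatially
autocorrelated chromatin state, overlapping or nested transcripts —
bounds what passing tests show: they validate the arithmetic, the
window logic, and recovery of an idealized BEST signal at realistic
densities, not robustness to library artifacts in real data.

## Known limitations

* The classifier's histogram form (quantile bins, log1p, Laplace
  smoothing) is one reasonable choice among several; results on real
  data can be sensitive to the bin count for small training sets.
* Intergenic training regions may rarely fall on genuine unannotated
  signal; with real annotations this mildly contaminates class N.
* One prediction per fixed 2-kb tile means a BEST event straddling a
  tile boundary can split its signal between two windows; strong events
  still score, weak ones may be missed.
* Pausing-index window sizes are conventions, not estimates; only the
  sign of its correlation with expression is asserted.
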