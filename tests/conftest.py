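"""Shared fixtures: tiny hand-built tracks plus one small generated dataset
with its trained model, reused across test modules."""

import numpy as np
import pytest

import bestscan as bs
from bestscan import active_genes as ag
from bestscan import classifier as cls
from bestscan import io as bio


def make_track(**per_chrom):
    """make_track(chr1={'+': [1, 5], '-': [9]}) -> StrandedReadTrack"""
    return bio.StrandedReadTrack(
        {
            chrom: {s: np.array(p, dtype=np.int64) for s, p in strands.items()}
            for chrom, strands in per_chrom.items()
        }
    )


@pytest.fixture(scope="session")
def unit_map():
    return bio.MapabilityTrack.uniform(1.0)


SMALL_CONFIG = dict(
    seed=11,
    chrom_sizes={"chrA": 1_500_000, "chrB": 1_500_000},
    n_genes=40,
    n_planted_best=10,
    gene_spacing_bp=12_000,
    planted_clearance_bp=13_000,
)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("small_ds")
    cfg = bs.SyntheticConfig(**SMALL_CONFIG)
    return bs.generate(cfg, str(outdir))


@pytest.fixture(scope="session")
def small_loaded(small_dataset):
    """Parsed inputs of the small dataset."""
    ds = small_dataset
    transcripts = bio.read_transcripts(ds.genes_path)
    track = bio.read_stranded_reads(ds.reads_plus_path, ds.reads_minus_path)
    maptrack = bio.read_mapability(ds.mapability_path)
    sizes = bio.read_chrom_sizes(ds.chrom_sizes_path)
    labels = bio.read_expression_labels(ds.labels_path)
    k4 = bio.read_peaks(ds.peak_paths["h3k4me3"], "h3k4me3")
    return dict(ds=ds, transcripts=transcripts, track=track, maptrack=maptrack,
                sizes=sizes, labels=labels, h3k4me3=k4)


@pytest.fixture(scope="session")
def small_active(small_loaded):
    d = small_loaded
    validated = [t for t in d["transcripts"] if t.is_validated_mrna]
    dens = ag.transcript_densities(validated, d["track"], d["maptrack"])
    usable = {k: dens[k].value for k in d["labels"]
              if k in dens and dens[k].defined}
    roc = ag.maximal_accuracy_cutoff(usable, {k: d["labels"][k] for k in usable})
    active_acc, _ = ag.call_active_transcripts(dens, roc.cutoff, validated)
    return dict(validated=validated, densities=dens, roc=roc,
                active=[t for t in validated if t.accession in active_acc])


@pytest.fixture(scope="session")
def small_model(small_loaded, small_active):
    d = small_loaded
    windows = cls.build_training_windows(
        small_active["active"], d["sizes"], seed=11,
        all_transcripts=d["transcripts"],
    )
    feats = cls.extract_training_features(
        windows, d["track"], d["maptrack"], d["sizes"]
    )
    return cls.fit_model(feats, min_class_size=20)


@pytest.fixture(scope="session")
def small_scan(small_loaded, small_model):
    d = small_loaded
    mask = cls.exclusion_mask(d["transcripts"], d["h3k4me3"])
    preds = cls.scan_genome(small_model, d["track"], d["maptrack"], mask, d["sizes"])
    return dict(mask=mask, predictions=preds)


def random_model(rng, n_bins=5):
    """A random but valid ClassConditionalModel for oracle tests."""
    edges = [np.sort(rng.normal(size=n_bins - 1)) for _ in range(6)]
    masses = {}
    for c in cls.CLASSES:
        ms = []
        for _ in range(6):
            raw = rng.random(n_bins) + 0.05
            ms.append(raw / raw.sum())
        masses[c] = ms
    priors_raw = rng.random(3) + 0.1
    priors_raw /= priors_raw.sum()
    priors = dict(zip(cls.CLASSES, priors_raw.tolist()))
    return cls.ClassConditionalModel(
        priors=priors, interior_edges=edges, masses=masses,
        n_bins=n_bins, pseudocount=1.0, ratio_pseudocount=0.1,
    )


def random_feature_vector(rng):
    return cls.FeatureVector(*np.abs(rng.normal(scale=3.0, size=6)).tolist())
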