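"""Feature extraction, model fitting, posterior/LOD scoring, exclusion
mask, and the genome scan."""

import math

import numpy as np
import pytest

import bestscan as bs
from bestscan import GenomicInterval, MapabilityTrack, PeakSet, Transcript
from bestscan import classifier as cls
from bestscan.classifier import (
    FeatureUndefinedError,
    FeatureVector,
    _smoothed_histogram,
    build_training_windows,
    exclusion_mask,
    extract_features,
    fit_model,
)

from conftest import make_track, random_feature_vector, random_model


def tx(acc, chrom, start, end, strand):
    return Transcript(acc, acc, GenomicInterval(chrom, start, end, strand), True)


class TestExtractFeatures:
    def test_sense_ratio_to_3prime(self, unit_map):
        # window [2000,4000)+: 10 sense reads (5/kb); 3' flank [4000,6000): 2
        # (1/kb); 5' flank [0,2000): 4 (2/kb)
        track = make_track(chr1={"+": [2500] * 10 + [4500] * 2 + [500] * 4, "-": []})
        w = GenomicInterval("chr1", 2000, 4000, "+")
        fv = extract_features(track, w, unit_map, ratio_pseudocount=0.0)
        assert fv.f1 == pytest.approx(5.0)
        assert fv.f3 == pytest.approx(5.0)
        assert fv.f5 == pytest.approx(2.5)

    def test_uniform_density_gives_unit_ratios(self, unit_map):
        reads = list(range(0, 6000, 100))
        track = make_track(chr1={"+": reads, "-": reads})
        w = GenomicInterval("chr1", 2000, 4000, "+")
        fv = extract_features(track, w, unit_map, ratio_pseudocount=0.0)
        for f in (fv.f3, fv.f4, fv.f5, fv.f6):
            assert f == pytest.approx(1.0)

    def test_zero_reads_pseudocount_identity(self, unit_map):
        track = make_track(chr1={"+": [], "-": []})
        w = GenomicInterval("chr1", 2000, 4000, "+")
        fv = extract_features(track, w, unit_map, ratio_pseudocount=0.1)
        assert fv.f1 == 0.0 and fv.f2 == 0.0
        assert (fv.f3, fv.f4, fv.f5, fv.f6) == (1.0, 1.0, 1.0, 1.0)

    def test_strand_relative_neighbors_swap_on_minus(self, unit_map):
        # sense(-) = minus reads; 3' of a minus window is the LEFT flank
        track = make_track(chr1={"+": [], "-": [2500] * 10 + [500] * 2 + [4500] * 4})
        w = GenomicInterval("chr1", 2000, 4000, "-")
        fv = extract_features(track, w, unit_map, ratio_pseudocount=0.0)
        assert fv.f1 == pytest.approx(5.0)
        assert fv.f3 == pytest.approx(5.0 / 1.0)  # left flank: 2 reads -> 1/kb
        assert fv.f5 == pytest.approx(5.0 / 2.0)  # right flank: 4 reads -> 2/kb

    def test_flank_off_chromosome_refused(self, unit_map):
        track = make_track(chr1={"+": [], "-": []})
        with pytest.raises(FeatureUndefinedError):
            extract_features(track, GenomicInterval("chr1", 0, 2000, "+"), unit_map)

    def test_low_mapability_refused(self):
        track = make_track(chr1={"+": [3000], "-": []})
        m = MapabilityTrack.uniform(0.01)
        with pytest.raises(FeatureUndefinedError):
            extract_features(track, GenomicInterval("chr1", 2000, 4000, "+"), m)

    def test_ratio_features_invariant_under_count_scaling(self, unit_map):
        rng = np.random.default_rng(0)
        reads = rng.integers(0, 6000, size=300).tolist()
        t1 = make_track(chr1={"+": reads, "-": reads[:100]})
        t3 = t1.scaled(3)
        w = GenomicInterval("chr1", 2000, 4000, "+")
        f1 = extract_features(t1, w, unit_map, ratio_pseudocount=0.0)
        f3 = extract_features(t3, w, unit_map, ratio_pseudocount=0.0)
        assert (f3.f3, f3.f4, f3.f5, f3.f6) == pytest.approx(
            (f1.f3, f1.f4, f1.f5, f1.f6))
        assert f3.f1 == pytest.approx(3 * f1.f1)


class TestFitModel:
    def test_laplace_smoothed_single_bin_mass(self):
        # 90 values in one of 10 bins, pseudocount 1 -> 91/100 there, 1/100 each
        edges = np.arange(1.0, 10.0)  # 9 interior edges -> 10 bins
        values = np.full(90, 3.5)
        masses = _smoothed_histogram(values, edges, 10, 1.0)
        assert masses[3] == pytest.approx(91 / 100)
        assert np.allclose(np.delete(masses, 3), 1 / 100)

    def _training(self, rng, n=60):
        return {
            c: [FeatureVector(*np.abs(rng.normal(size=6, scale=s)).tolist())
                for _ in range(n)]
            for c, s in zip(cls.CLASSES, (5.0, 2.0, 0.3))
        }

    def test_masses_sum_to_one(self):
        model = fit_model(self._training(np.random.default_rng(0)))
        for c in cls.CLASSES:
            for m in model.masses[c]:
                assert m.sum() == pytest.approx(1.0, abs=1e-9)
                assert (m > 0).all()

    def test_identical_classes_identical_distributions(self):
        rng = np.random.default_rng(1)
        shared = [FeatureVector(*np.abs(rng.normal(size=6)).tolist())
                  for _ in range(60)]
        model = fit_model({c: list(shared) for c in cls.CLASSES})
        for j in range(6):
            assert np.allclose(model.masses["B"][j], model.masses["E"][j])
            assert np.allclose(model.masses["B"][j], model.masses["N"][j])

    def test_small_class_rejected(self):
        training = self._training(np.random.default_rng(2), n=10)
        with pytest.raises(ValueError, match="training windows"):
            fit_model(training)

    def test_priors_equal(self):
        model = fit_model(self._training(np.random.default_rng(3)))
        assert list(model.priors.values()) == pytest.approx([1 / 3] * 3)


def direct_product_scores(model, fv):
    """Brute-force oracle: plain products of priors and bin masses, no
    log-space arithmetic."""
    x = np.log1p(fv.as_array())
    scores = {}
    for c in cls.CLASSES:
        s = model.priors[c]
        for j in range(6):
            edges = model.interior_edges[j]
            b = 0
            while b < edges.size and x[j] > edges[b]:
                b += 1
            s *= model.masses[c][j][b]
        scores[c] = s
    return scores


class TestPosteriorAndLod:
    def test_equal_likelihoods_tie_breaks_to_N(self):
        rng = np.random.default_rng(0)
        shared = [FeatureVector(*np.abs(rng.normal(size=6)).tolist())
                  for _ in range(60)]
        model = fit_model({c: list(shared) for c in cls.CLASSES})
        post, label = model.posterior(random_feature_vector(rng))
        assert post == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert label == "N"

    def test_matches_direct_product_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            model = random_model(rng)
            fv = random_feature_vector(rng)
            oracle = direct_product_scores(model, fv)
            total = sum(oracle.values())
            post, _ = model.posterior(fv)
            assert post == pytest.approx(
                tuple(oracle[c] / total for c in cls.CLASSES), abs=1e-9)
            assert model.lod(fv) == pytest.approx(
                math.log(oracle["B"] / max(oracle["E"], oracle["N"])), abs=1e-9)

    def test_lod_zero_when_B_equals_best_other(self):
        rng = np.random.default_rng(1)
        shared = [FeatureVector(*np.abs(rng.normal(size=6)).tolist())
                  for _ in range(60)]
        model = fit_model({c: list(shared) for c in cls.CLASSES})
        assert model.lod(random_feature_vector(rng)) == pytest.approx(0.0)

    def test_lod_threshold_is_strict(self):
        # LOD exactly 2.5 is NOT high confidence (the rule is LOD > 2.5)
        assert not (2.5 > 2.5)
        rng = np.random.default_rng(2)
        model = random_model(rng)
        fv = random_feature_vector(rng)
        lod = model.lod(fv)
        assert not (lod > lod)  # boundary semantics carried by strict >

    def test_class_B_iff_positive_lod_under_equal_priors(self):
        rng = np.random.default_rng(5)
        base = random_model(rng)
        model = cls.ClassConditionalModel(
            priors={c: 1 / 3 for c in cls.CLASSES},
            interior_edges=base.interior_edges, masses=base.masses,
            n_bins=base.n_bins, pseudocount=1.0, ratio_pseudocount=0.1)
        for _ in range(300):
            fv = random_feature_vector(rng)
            _, label = model.posterior(fv)
            lod = model.lod(fv)
            assert (label == "B") == (lod > 0)

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        model = random_model(rng)
        path = str(tmp_path / "model.json")
        model.save(path)
        back = cls.ClassConditionalModel.load(path)
        for _ in range(20):
            fv = random_feature_vector(rng)
            assert back.lod(fv) == pytest.approx(model.lod(fv), abs=1e-12)


class TestExclusionMask:
    def test_point_anchor_intervals_exact(self):
        # TSS 100,000 -> [93000, 107000); gene end 199,999 -> [192999, 206999)
        mask = exclusion_mask([tx("NM_1", "chr1", 100_000, 200_000, "+")],
                              radius_bp=7000)
        assert mask.intervals("chr1") == [(93_000, 107_000), (192_999, 206_999)]

    def test_overlapping_intervals_merged(self):
        ts = [tx("NM_1", "chr1", 10_000, 16_000, "+")]
        mask = exclusion_mask(ts, radius_bp=7000)
        # TSS 10,000 and end 15,999 neighborhoods overlap -> one interval
        assert mask.intervals("chr1") == [(3_000, 22_999)]

    def test_h3k4me3_peaks_included(self):
        peaks = PeakSet("k4", [GenomicInterval("chr2", 50_000, 50_400)])
        mask = exclusion_mask([], peaks, radius_bp=7000)
        assert mask.intervals("chr2") == [(43_000, 57_400)]

    def test_empty_inputs_empty_mask(self):
        mask = exclusion_mask([], None)
        assert mask.chroms == []
        assert not mask.intersects("chr1", 0, 10**9)


class TestTrainingWindows:
    def test_centering_arithmetic(self):
        sizes = {"chr1": 1_000_000}
        w = build_training_windows([tx("NM_1", "chr1", 10_000, 20_000, "+")],
                                   sizes, n_intergenic=1, seed=0)
        assert (w["B"][0].start, w["B"][0].end, w["B"][0].strand) == (9_000, 11_000, "+")
        assert (w["E"][0].start, w["E"][0].end, w["E"][0].strand) == (14_000, 16_000, "+")

    def test_minus_strand_tss_window(self):
        sizes = {"chr1": 1_000_000}
        w = build_training_windows([tx("NM_1", "chr1", 10_000, 20_000, "-")],
                                   sizes, n_intergenic=1, seed=0)
        # TSS at 19,999 -> window centered there
        assert (w["B"][0].start, w["B"][0].end) == (18_999, 20_999)

    def test_fixed_seed_reproducible_intergenic(self):
        sizes = {"chr1": 2_000_000}
        ts = [tx("NM_1", "chr1", 10_000, 20_000, "+")]
        w1 = build_training_windows(ts, sizes, n_intergenic=20, seed=5)
        w2 = build_training_windows(ts, sizes, n_intergenic=20, seed=5)
        assert w1["N"] == w2["N"]
        w3 = build_training_windows(ts, sizes, n_intergenic=20, seed=6)
        assert w1["N"] != w3["N"]

    def test_saturated_genome_placement_error(self):
        sizes = {"chr1": 30_000}
        ts = [tx("NM_1", "chr1", 0, 30_000, "+")]
        with pytest.raises(RuntimeError, match="could not place"):
            build_training_windows(ts, sizes, n_intergenic=5, seed=0)

    def test_intergenic_avoid_all_known_transcripts(self):
        sizes = {"chr1": 500_000}
        active = [tx("NM_1", "chr1", 10_000, 20_000, "+")]
        other = [tx("NR_2", "chr1", 100_000, 400_000, "+")]
        w = build_training_windows(active, sizes, n_intergenic=30, seed=1,
                                   all_transcripts=active + other)
        for win in w["N"]:
            for t in active + other:
                assert not win.overlaps(
                    GenomicInterval(t.chrom, t.interval.start, t.interval.end))


class TestScan:
    def test_zero_read_track_no_high_confidence(self, small_loaded, small_model):
        d = small_loaded
        empty = make_track(**{c: {"+": [], "-": []} for c in d["sizes"]})
        mask = exclusion_mask(d["transcripts"], d["h3k4me3"])
        preds = cls.scan_genome(small_model, empty, d["maptrack"], mask, d["sizes"])
        assert sum(p.high_confidence for p in preds) == 0

    def test_masked_windows_absent(self, small_loaded, small_scan):
        mask = small_scan["mask"]
        for p in small_scan["predictions"]:
            w = p.window
            assert not mask.intersects(w.chrom, w.start - w.length, w.end + w.length)

    def test_one_prediction_per_genomic_window(self, small_scan):
        seen = {(p.window.chrom, p.window.start) for p in small_scan["predictions"]}
        assert len(seen) == len(small_scan["predictions"])

    def test_class_B_iff_lod_positive_in_scan(self, small_scan):
        for p in small_scan["predictions"]:
            assert (p.label == "B") == (p.lod > 0)

    def test_recovers_planted_loci(self, small_loaded, small_scan):
        sens, prec = bs.truth_overlap_report(
            small_scan["predictions"], small_loaded["ds"].truth)
        assert sens >= 0.8
        assert prec >= 0.8
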