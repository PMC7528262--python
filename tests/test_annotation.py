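import numpy as np
import pytest

from cnvdiff.annotation import (
    WindowDensity,
    breed_sharing,
    detect_clusters,
    feature_class_enrichment,
    overlap_genes,
    shared_by_all,
    specific_sequences,
    subspecies_comparison,
    window_density,
)
from cnvdiff.intervals import GenomicInterval
from cnvdiff.io_formats import Feature, FeatureSet

from conftest import iv, make_cnvr, perbase_cover


class TestOverlapGenes:
    def feats(self):
        return FeatureSet(
            [
                Feature(iv("chr1", 199, 300), "exon", "g1"),
                Feature(iv("chr1", 300, 400), "intron", "g1"),
                Feature(iv("chr1", 200, 300), "exon", "g2"),
                Feature(iv("chr2", 0, 100), "exon", "g3"),
            ]
        )

    def test_single_bp_overlap_counts(self):
        genes, exon_genes = overlap_genes([make_cnvr("chr1", 100, 200)], self.feats())
        assert genes == {"g1"}
        assert exon_genes == {"g1"}

    def test_half_open_touching_does_not_count(self):
        feats = FeatureSet([Feature(iv("chr1", 200, 300), "exon", "g2")])
        genes, _ = overlap_genes([make_cnvr("chr1", 100, 200)], feats)
        assert genes == set()

    def test_intron_only_overlap_not_exonic(self):
        genes, exon_genes = overlap_genes([make_cnvr("chr1", 350, 360)], self.feats())
        assert genes == {"g1"}
        assert exon_genes == set()

    def test_matches_perbase_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            cnvrs = [
                make_cnvr("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 9_000, 5), rng.integers(1, 800, 5))
            ]
            feats = []
            for g in range(6):
                s = int(rng.integers(0, 9_500))
                feats.append(Feature(iv("chr1", s, s + int(rng.integers(1, 400))),
                                     str(rng.choice(["exon", "intron"])), f"g{g}"))
            fs = FeatureSet(feats)
            genes, exon_genes = overlap_genes(cnvrs, fs)
            cover = perbase_cover([r.interval for r in cnvrs], 10_000)
            want, want_exon = set(), set()
            for f in fs.features:
                if cover[f.interval.start : f.interval.end].any():
                    want.add(f.gene_id)
                    if f.feature_class == "exon":
                        want_exon.add(f.gene_id)
            assert genes == want
            assert exon_genes == want_exon


class TestEnrichment:
    def full_classes(self, chrom_len):
        # every class present somewhere so no class errors out
        return [
            Feature(iv("chr1", 8_000, 8_100), "intron", "gx"),
            Feature(iv("chr1", 8_200, 8_300), "lncRNA", "gy"),
            Feature(iv("chr1", 8_400, 8_500), "pseudogene", "gz"),
        ]

    def test_oe_ratio_arithmetic(self):
        # exon class covers 10% of a 10 kb genome; CNVRs spend 5% of their bp in it
        features = FeatureSet(
            [Feature(iv("chr1", 0, 1_000), "exon", "g1")] + self.full_classes(10_000)
        )
        # CNVR bp total 2000, of which 100 in the exon class
        cnvrs = [make_cnvr("chr1", 900, 2_900)]
        oe = feature_class_enrichment(cnvrs, features, {"chr1": 10_000})
        assert oe["exon"] == pytest.approx((100 / 2_000) / (1_000 / 10_000))
        assert oe["exon"] == pytest.approx(0.5)

    def test_uniform_cnvrs_give_oe_one(self):
        features = FeatureSet(
            [Feature(iv("chr1", 2_000, 3_000), "exon", "g1")] + self.full_classes(10_000)
        )
        cnvrs = [make_cnvr("chr1", 0, 10_000)]  # CNVR covers everything
        oe = feature_class_enrichment(cnvrs, features, {"chr1": 10_000})
        for v in oe.values():
            assert v == pytest.approx(1.0)

    def test_zero_bp_class_errors(self):
        features = FeatureSet([Feature(iv("chr1", 0, 100), "exon", "g1")])
        with pytest.raises(ValueError, match="zero genomic bp"):
            feature_class_enrichment([make_cnvr("chr1", 0, 50)], features, {"chr1": 1_000})

    def test_matches_perbase_oracle(self):
        rng = np.random.default_rng(33)
        genome = {"chr1": 10_000}
        for _ in range(10):
            cnvrs = [
                make_cnvr("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 9_000, 4), rng.integers(1, 900, 4))
            ]
            feats = []
            for k, cls in enumerate(("exon", "intron", "lncRNA", "pseudogene")):
                for _ in range(3):
                    s = int(rng.integers(0, 9_000))
                    feats.append(Feature(iv("chr1", s, s + int(rng.integers(1, 700))), cls, f"g{k}"))
            fs = FeatureSet(feats)
            oe = feature_class_enrichment(cnvrs, fs, genome)
            cnvr_cover = perbase_cover([r.interval for r in cnvrs], 10_000)
            for cls in ("exon", "intron", "lncRNA", "pseudogene"):
                class_cover = perbase_cover(fs.by_class(cls), 10_000)
                observed = (cnvr_cover & class_cover).sum() / cnvr_cover.sum()
                expected = class_cover.sum() / 10_000
                assert oe[cls] == pytest.approx(observed / expected)


class TestWindowDensity:
    def test_fraction_and_cluster_membership(self):
        cnvrs = [make_cnvr("chr1", 0, 850_000)]
        densities = window_density(cnvrs, {"chr1": 2_000_000})
        assert densities[0].covered_bp == 850_000
        assert densities[0].covered_fraction == pytest.approx(0.85)
        clusters = detect_clusters(densities)
        assert clusters == [GenomicInterval("chr1", 0, 1_000_000)]

    def test_exact_threshold_not_cluster(self):
        cnvrs = [make_cnvr("chr1", 0, 800_000)]
        densities = window_density(cnvrs, {"chr1": 1_000_000})
        assert densities[0].covered_fraction == pytest.approx(0.8)
        assert detect_clusters(densities) == []

    def test_adjacent_windows_merge(self):
        cnvrs = [make_cnvr("chr1", 0, 1_900_000)]
        densities = window_density(cnvrs, {"chr1": 3_000_000})
        clusters = detect_clusters(densities)
        assert clusters == [GenomicInterval("chr1", 0, 2_000_000)]

    def test_short_terminal_window_true_denominator(self):
        cnvrs = [make_cnvr("chr1", 1_000_000, 1_400_000)]
        densities = window_density(cnvrs, {"chr1": 1_500_000})
        assert densities[-1].window.length() == 500_000
        assert densities[-1].covered_fraction == pytest.approx(0.8)

    def test_windows_tile_without_overlap(self):
        densities = window_density([], {"chr1": 2_500_000, "chr2": 999_999})
        for a, b in zip(densities, densities[1:]):
            if a.window.chrom == b.window.chrom:
                assert a.window.end == b.window.start
        assert sum(d.window.length() for d in densities) == 2_500_000 + 999_999

    def test_conservation_and_perbase_oracle(self):
        rng = np.random.default_rng(44)
        genome = {"chr1": 100_000}
        cnvrs = [
            make_cnvr("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 95_000, 12), rng.integers(1, 8_000, 12))
        ]
        densities = window_density(cnvrs, genome, window=10_000)
        cover = perbase_cover([r.interval for r in cnvrs], 100_000)
        for d in densities:
            assert d.covered_bp == int(cover[d.window.start : d.window.end].sum())
        assert sum(d.covered_bp for d in densities) == int(cover.sum())


class TestSharing:
    def test_shared_by_all_breeds(self, sample_table):
        cnvrs = [
            make_cnvr("chr1", 0, 100, samples=["t1", "t3", "i1", "i3"]),  # all 4 breeds
            make_cnvr("chr1", 200, 300, samples=["t1", "t2"]),            # Angus only
        ]
        summary = breed_sharing(cnvrs, sample_table)
        all_breeds = frozenset(sample_table.breeds)
        assert shared_by_all(summary, all_breeds) == 1

    def test_private_pattern(self, sample_table):
        summary = breed_sharing([make_cnvr("chr1", 0, 100, samples=["i1"])], sample_table)
        assert summary.pattern_counts == {frozenset({"Nelore"}): 1}

    def test_pattern_counts_hand_enumeration(self, sample_table):
        cnvrs = [
            make_cnvr("chr1", 0, 100, samples=["t1", "i1"]),
            make_cnvr("chr1", 200, 300, samples=["t1", "i2"]),
            make_cnvr("chr1", 400, 500, samples=["t3"]),
            make_cnvr("chr1", 600, 700, samples=["t3", "t1"]),
            make_cnvr("chr1", 800, 900, samples=["i3"]),
        ]
        summary = breed_sharing(cnvrs, sample_table)
        assert summary.pattern_counts == {
            frozenset({"Angus", "Nelore"}): 2,
            frozenset({"NDama"}): 1,
            frozenset({"NDama", "Angus"}): 1,
            frozenset({"Gir"}): 1,
        }


class TestSubspeciesComparison:
    def test_four_cnvr_fixture(self, sample_table):
        cnvrs = [
            make_cnvr("chr1", 0, 100, samples=["t1", "i1"]),
            make_cnvr("chr1", 200, 300, samples=["t2", "i2"]),
            make_cnvr("chr1", 400, 500, samples=["t1", "t2"]),
            make_cnvr("chr1", 600, 700, samples=["i1", "i2"]),
        ]
        shared, t_spec, i_spec, pct = subspecies_comparison(cnvrs, sample_table)
        assert (len(shared), len(t_spec), len(i_spec)) == (2, 1, 1)
        assert pct == 50.00

    def test_all_shared(self, sample_table):
        cnvrs = [make_cnvr("chr1", i * 200, i * 200 + 100, samples=["t1", "i1"]) for i in range(3)]
        *_, pct = subspecies_comparison(cnvrs, sample_table)
        assert pct == 100.00

    def test_partition_is_exhaustive(self, sample_table):
        rng = np.random.default_rng(55)
        pool = sample_table.samples
        cnvrs = []
        for k in range(40):
            picks = list(rng.choice(pool, size=rng.integers(1, 5), replace=False))
            cnvrs.append(make_cnvr("chr1", k * 300, k * 300 + 100, samples=picks))
        shared, t_spec, i_spec, _ = subspecies_comparison(cnvrs, sample_table)
        assert len(shared) + len(t_spec) + len(i_spec) == len(cnvrs)


class TestSpecificSequences:
    def test_length_and_depth_pass(self):
        kept, total = specific_sequences([(iv("chr1", 0, 600), 2)])
        assert kept == [iv("chr1", 0, 600)]
        assert total == 600

    def test_short_dropped(self):
        kept, total = specific_sequences([(iv("chr1", 0, 400), 5)])
        assert kept == [] and total == 0

    def test_low_depth_dropped(self):
        kept, _ = specific_sequences([(iv("chr1", 0, 10_000), 1)])
        assert kept == []

    def test_book_ended_merge_and_length_filter(self):
        runs = [(iv("chr1", 0, 300), 2), (iv("chr1", 300, 400), 3)]
        kept, total = specific_sequences(runs)
        assert kept == [] and total == 0
        runs.append((iv("chr1", 400, 650), 2))
        kept, total = specific_sequences(runs)
        assert kept == [iv("chr1", 0, 650)]
        assert total == 650

    def test_exactly_500_dropped(self):
        kept, _ = specific_sequences([(iv("chr1", 0, 500), 2)])
        assert kept == []

    def test_negative_depth_errors(self):
        with pytest.raises(ValueError, match="negative depth"):
            specific_sequences([(iv("chr1", 0, 600), -1)])
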