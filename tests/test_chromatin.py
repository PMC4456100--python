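import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tespread.chromatin import (
    DensityTrack,
    clamp_track,
    gene_h3k9_density,
    interval_mean_density,
    matched_null_ensemble,
    stage_enrichment_count,
    te_flank_decay_profile,
    window_contrast,
)
from tespread.genome import (
    ChromSpec,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TEInsertion,
    intergenic_intervals,
)
from conftest import brute_force_interval_mean


def track_from(edges, values, chrom="chr1", stage="s"):
    return DensityTrack(
        stage=stage,
        data={chrom: (np.asarray(edges, dtype=np.int64), np.asarray(values, float))},
    )


class TestClamp:
    def test_negative_assigned_zero_others_kept(self):
        t = track_from([0, 100, 200, 300], [-0.3, 0.7, 0.0])
        c = clamp_track(t)
        assert list(c.data["chr1"][1]) == [0.0, 0.7, 0.0]

    def test_idempotent(self):
        t = track_from([0, 100, 200], [-1.0, 2.0])
        once = clamp_track(t)
        twice = clamp_track(once)
        np.testing.assert_array_equal(once.data["chr1"][1], twice.data["chr1"][1])


class TestIntervalMean:
    def test_constant_track(self):
        t = track_from([0, 1_000], [2.0])
        assert interval_mean_density(t, GenomicInterval("chr1", 37, 912)) == 2.0

    def test_two_step_weighted(self):
        t = track_from([0, 100, 400], [1.0, 3.0])
        got = interval_mean_density(t, GenomicInterval("chr1", 0, 400))
        assert got == pytest.approx((100 * 1 + 300 * 3) / 400)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_per_bp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cuts = np.sort(rng.choice(np.arange(1, 2_000), size=8, replace=False))
        edges = np.concatenate([[0], cuts, [2_000]])
        values = rng.uniform(0, 3, size=len(edges) - 1)
        t = track_from(edges, values)
        start = int(rng.integers(0, 1_900))
        end = int(rng.integers(start + 1, 2_000))
        got = interval_mean_density(t, GenomicInterval("chr1", start, end))
        assert got == pytest.approx(
            brute_force_interval_mean(edges, values, start, end)
        )

    def test_off_chromosome_raises(self):
        t = track_from([0, 100], [1.0])
        with pytest.raises(ValueError):
            interval_mean_density(t, GenomicInterval("chr1", 50, 200))


class TestGeneDensity:
    def test_single_exon_equals_interval_mean(self):
        t = track_from([0, 500, 1_000], [1.0, 3.0])
        g = GeneModel(
            "g", GenomicInterval("chr1", 100, 400),
            [GenomicInterval("chr1", 100, 400)],
        )
        assert gene_h3k9_density(t, g) == interval_mean_density(t, g.span)

    def test_exon_weighted_mean(self):
        # exons 100 bp @ 1.0 and 300 bp @ 2.0 -> 1.75
        t = track_from([0, 200, 1_000], [1.0, 2.0])
        g = GeneModel(
            "g", GenomicInterval("chr1", 100, 800),
            [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 500, 800)],
        )
        assert gene_h3k9_density(t, g) == pytest.approx(1.75)

    def test_multi_exon_matches_per_bp_oracle(self):
        rng = np.random.default_rng(5)
        cuts = np.sort(rng.choice(np.arange(1, 5_000), size=12, replace=False))
        edges = np.concatenate([[0], cuts, [5_000]])
        values = rng.uniform(0, 2, size=len(edges) - 1)
        t = track_from(edges, values)
        g = GeneModel(
            "g", GenomicInterval("chr1", 200, 4_800),
            [
                GenomicInterval("chr1", 200, 900),
                GenomicInterval("chr1", 1_500, 2_000),
                GenomicInterval("chr1", 3_000, 4_800),
            ],
        )
        per_bp = np.repeat(values, np.diff(edges).astype(int))
        mask = np.zeros(5_000, bool)
        for e in g.exons:
            mask[e.start : e.end] = True
        assert gene_h3k9_density(t, g) == pytest.approx(float(per_bp[mask].mean()))


def _te_only_annotation(te_positions, length=200_000, te_len=500):
    tes = [
        TEInsertion(f"t{i}", "FAM", GenomicInterval("chr1", p, p + te_len))
        for i, p in enumerate(te_positions)
    ]
    chrom = ChromSpec("chr1", length, [GenomicInterval("chr1", 0, length)])
    return GenomeAnnotation(chroms={"chr1": chrom}, genes=[], tes=tes)


class TestDecayProfile:
    def test_uniform_track_gives_flat_profile(self):
        ann = _te_only_annotation([50_000, 120_000])
        t = track_from([0, 200_000], [1.5])
        prof = te_flank_decay_profile(ann.tes, t, intergenic_intervals(ann))
        assert prof.n_flanks == 4
        np.testing.assert_allclose(prof.mean, 1.5)
        np.testing.assert_allclose(prof.median, 1.5)

    def test_flank_with_gene_dropped_whole(self):
        ann = _te_only_annotation([50_000])
        # a gene 6 kb into the right flank kills that whole flank
        gene = GeneModel(
            "g", GenomicInterval("chr1", 56_500, 58_000),
            [GenomicInterval("chr1", 56_500, 58_000)],
        )
        ann.genes.append(gene)
        t = track_from([0, 200_000], [1.0])
        prof = te_flank_decay_profile(ann.tes, t, intergenic_intervals(ann))
        assert prof.n_flanks == 1  # left only
        assert all(n == 1 for n in prof.n)

    def test_off_chromosome_flank_skipped(self):
        ann = _te_only_annotation([5_000])  # left flank would start at -5,000
        t = track_from([0, 200_000], [1.0])
        prof = te_flank_decay_profile(ann.tes, t, intergenic_intervals(ann))
        assert prof.n_flanks == 1

    def test_window_means_match_direct_slicing_oracle(self):
        rng = np.random.default_rng(11)
        ann = _te_only_annotation([50_000, 130_000])
        edges = np.arange(0, 200_001, 100)
        values = rng.uniform(0, 1, size=len(edges) - 1)
        t = track_from(edges, values)
        prof = te_flank_decay_profile(ann.tes, t, intergenic_intervals(ann))
        per_bp = np.repeat(values, 100)
        for w in range(10):
            expected = []
            for te in ann.tes:
                s, e = te.span.start, te.span.end
                expected.append(per_bp[s - (w + 1) * 1_000 : s - w * 1_000].mean())
                expected.append(per_bp[e + w * 1_000 : e + (w + 1) * 1_000].mean())
            assert sorted(prof.windows[w]) == pytest.approx(sorted(expected))


class TestMatchedNull:
    def test_zero_reps_empty(self):
        ann = _te_only_annotation([50_000])
        t = track_from([0, 200_000], [1.0])
        ens = matched_null_ensemble(
            ann.tes, ann, t, intergenic_intervals(ann), n_reps=0, seed=1
        )
        assert ens.profiles == [] and ens.segments == []

    def test_segment_constraints_and_length_multiset(self, dataset, clamped_tracks):
        ann = dataset.annotation
        mask = intergenic_intervals(ann)
        ens = matched_null_ensemble(
            ann.tes, ann, clamped_tracks[0], mask, n_reps=3, seed=9
        )
        te_lengths = sorted(t.length for t in ann.tes)
        for segs in ens.segments:
            assert sorted(s.length for s in segs) == te_lengths
            for te, seg in zip(ann.tes, segs):
                assert seg.chrom == te.span.chrom
                chrom = ann.chroms[te.span.chrom]
                b = chrom.locality_bin(te.span.midpoint)
                lo, hi = chrom.bin_bounds(b)
                assert lo <= seg.start and seg.end <= hi

    def test_seed_reproducibility_bit_identical(self):
        ann = _te_only_annotation([50_000, 120_000])
        t = track_from([0, 200_000], [1.0])
        mask = intergenic_intervals(ann)
        a = matched_null_ensemble(ann.tes, ann, t, mask, n_reps=4, seed=33)
        b = matched_null_ensemble(ann.tes, ann, t, mask, n_reps=4, seed=33)
        assert [
            (s.chrom, s.start, s.end) for segs in a.segments for s in segs
        ] == [(s.chrom, s.start, s.end) for segs in b.segments for s in segs]

    def test_uniform_track_observed_inside_null_band(self):
        rng = np.random.default_rng(2)
        ann = _te_only_annotation(list(range(30_000, 170_000, 20_000)))
        edges = np.arange(0, 200_001, 100)
        values = rng.uniform(0.9, 1.1, size=len(edges) - 1)
        t = track_from(edges, values)
        mask = intergenic_intervals(ann)
        prof = te_flank_decay_profile(ann.tes, t, mask)
        ens = matched_null_ensemble(ann.tes, ann, t, mask, n_reps=200, seed=4)
        lo, hi = ens.window_percentile_band("median")
        assert lo[0] <= prof.median[0] <= hi[0]

    def test_te_longer_than_bin_falls_back_to_chromosome(self, caplog):
        chrom = ChromSpec(
            "chr1", 200_000, [GenomicInterval("chr1", 0, 200_000)], bin_size=10_000
        )
        te = TEInsertion("big", "FAM", GenomicInterval("chr1", 50_000, 80_000))
        ann = GenomeAnnotation(chroms={"chr1": chrom}, genes=[], tes=[te])
        t = track_from([0, 200_000], [1.0])
        ens = matched_null_ensemble(
            [te], ann, t, intergenic_intervals(ann), n_reps=5, seed=0
        )
        for segs in ens.segments:
            assert segs[0].length == 30_000 and segs[0].end <= 200_000


class TestWindowContrast:
    def test_identical_samples_p_one(self):
        prof = te_flank_decay_profile([], track_from([0, 100], [1.0]), {})
        prof.windows[0] = np.array([1.0, 2.0, 3.0])
        prof.windows[9] = np.array([1.0, 2.0, 3.0])
        assert window_contrast(prof, 1, 10) == pytest.approx(1.0)

    def test_tiny_fixture_matches_rank_enumeration_oracle(self):
        prof = te_flank_decay_profile([], track_from([0, 100], [1.0]), {})
        prof.windows[0] = np.array([3.0, 4.0])
        prof.windows[9] = np.array([1.0, 2.0])
        # oracle: enumerate all C(4,2)=6 splits of ranks {1,2,3,4}; U for
        # group {3,4} is maximal in exactly 1; two-sided exact p = 2/6
        assert window_contrast(prof, 1, 10) == pytest.approx(2 / 6)

    def test_power_on_synthetic_spreading(self):
        rng = np.random.default_rng(8)
        prof = te_flank_decay_profile([], track_from([0, 100], [1.0]), {})
        prof.windows[0] = rng.normal(1.0, 0.2, size=60)   # near-TE elevated
        prof.windows[9] = rng.normal(0.3, 0.2, size=60)   # distal background
        assert window_contrast(prof, 1, 10) < 0.05

    def test_empty_window_raises(self):
        prof = te_flank_decay_profile([], track_from([0, 100], [1.0]), {})
        prof.windows[0] = np.array([1.0])
        with pytest.raises(ValueError):
            window_contrast(prof, 1, 10)


class TestStageEnrichmentCount:
    def test_extremes(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            rng.uniform(0.2, 0.8, size=(50, 9)),
            index=[f"g{i}" for i in range(50)],
        )
        df.loc["low"] = 0.0
        df.loc["high"] = 10.0
        counts = stage_enrichment_count(df, q=0.10)
        assert counts["low"] == 0 and counts["high"] == 9

    def test_matches_explicit_sorting_oracle(self):
        import pandas as pd

        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(size=(40, 4)))
        counts = stage_enrichment_count(df, q=0.25)
        for g in df.index:
            expected = sum(
                df.loc[g, c] >= np.quantile(df[c].to_numpy(), 0.75) for c in df.columns
            )
            assert counts[g] == expected

    def test_drop_low_all_stages(self):
        import pandas as pd

        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.uniform(0.5, 1.0, size=(40, 3)))
        df.iloc[:10] = 0.0  # uniformly silent genes
        counts = stage_enrichment_count(df, q=0.10, drop_low_all_stages=True)
        assert len(counts) == 30
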