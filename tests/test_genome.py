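import numpy as np
import pandas as pd
import pytest

from tespread.genome import (
    ChromSpec,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
    TEInsertion,
    apply_euchromatic_filter,
    distance_category,
    distance_tertiles,
    intergenic_intervals,
    is_intergenic,
    local_context,
    nearest_te,
    select_analysis_genes,
    te_counts_by_bin,
    te_gene_distance,
)
from tespread.io import read_gff3_genes, read_te_bed, write_gff3_genes, write_te_bed


def make_chrom(name="chr1", length=1_000_000, euch=None):
    euch = euch or [(10_000, length - 10_000)]
    return ChromSpec(
        name=name,
        length=length,
        euchromatin=[GenomicInterval(name, s, e) for s, e in euch],
    )


def gene(gid, start, end, exons=None, chrom="chr1"):
    exons = exons or [(start, end)]
    return GeneModel(
        gene_id=gid,
        span=GenomicInterval(chrom, start, end, "+"),
        exons=[GenomicInterval(chrom, s, e, "+") for s, e in exons],
    )


def te(tid, start, end, chrom="chr1", family="FAM"):
    return TEInsertion(tid, family, GenomicInterval(chrom, start, end, "+"))


class TestCoordinates:
    def test_gff3_roundtrip_preserves_one_based_coordinates(self, tmp_path):
        g = gene("g1", 100, 200, [(100, 140), (160, 200)])
        p = tmp_path / "x.gff3"
        write_gff3_genes([g], p)
        # on disk: 1-based closed, so the gene line reads 101..200
        gene_line = [l for l in p.read_text().splitlines() if "\tgene\t" in l][0]
        assert gene_line.split("\t")[3:5] == ["101", "200"]
        back = read_gff3_genes(p)
        assert back[0].span.start == 100 and back[0].span.end == 200
        assert [(e.start, e.end) for e in back[0].exons] == [(100, 140), (160, 200)]

    def test_longest_isoform_by_summed_exon_length(self, tmp_path):
        lines = [
            "##gff-version 3",
            "chr1\t.\tgene\t1001\t3000\t.\t+\t.\tID=g1",
            "chr1\t.\tmRNA\t1001\t3000\t.\t+\t.\tID=t1;Parent=g1",
            "chr1\t.\texon\t1001\t1900\t.\t+\t.\tParent=t1",      # 900 bp
            "chr1\t.\tmRNA\t1001\t3000\t.\t+\t.\tID=t2;Parent=g1",
            "chr1\t.\texon\t1001\t1600\t.\t+\t.\tParent=t2",      # 600 bp
            "chr1\t.\texon\t2401\t3000\t.\t+\t.\tParent=t2",      # 600 bp -> 1200 total
        ]
        p = tmp_path / "iso.gff3"
        p.write_text("\n".join(lines) + "\n")
        g = read_gff3_genes(p)[0]
        assert sum(e.length for e in g.exons) == 1200

    def test_bed_te_record_length(self, tmp_path):
        p = tmp_path / "te.bed"
        p.write_text("chr2L\t5000\t5500\tte_1|ROO\t0\t+\n")
        t = read_te_bed(p)[0]
        assert t.length == 500 and t.family == "ROO" and t.te_id == "te_1"

    def test_te_bed_roundtrip(self, tmp_path):
        t0 = te("teX", 123, 456, family="JOCKEY")
        p = tmp_path / "t.bed"
        write_te_bed([t0], p)
        t1 = read_te_bed(p)[0]
        assert (t1.te_id, t1.family, t1.span.start, t1.span.end) == (
            "teX", "JOCKEY", 123, 456,
        )


class TestEuchromaticFilter:
    def test_straddling_removed_contained_kept_chr4_dropped(self):
        chroms = {
            "chr1": make_chrom(),
            "4": make_chrom("4"),
        }
        ann = GenomeAnnotation(
            chroms=chroms,
            genes=[
                gene("ok", 50_000, 55_000),
                gene("on4", 50_000, 55_000, chrom="4"),
            ],
            tes=[
                te("straddle", 5_000, 15_000),  # crosses the boundary at 10 kb
                te("inside", 20_000, 21_000),
            ],
        )
        out = apply_euchromatic_filter(ann)
        assert [g.gene_id for g in out.genes] == ["ok"]
        assert [t.te_id for t in out.tes] == ["inside"]
        assert "4" not in out.chroms


class TestAnalysisGeneSelection:
    def test_exonic_te_excludes_intronic_te_keeps(self):
        ann = GenomeAnnotation(
            chroms={"chr1": make_chrom()},
            genes=[
                gene("exonic", 50_000, 60_000, [(50_000, 54_000), (56_000, 60_000)]),
                gene("intronic", 80_000, 90_000, [(80_000, 84_000), (86_000, 90_000)]),
            ],
            tes=[
                te("t_ex", 53_999, 54_500),   # 1-bp exon overlap
                te("t_in", 84_500, 85_000),   # wholly inside the intron
            ],
        )
        keep = [g.gene_id for g in select_analysis_genes(ann)]
        assert keep == ["intronic"]
        assert distance_category(ann.genes[1], ann.tes) == "in_gene"

    def test_flank_must_stay_in_euchromatin(self):
        # euchromatin ends at 990,000; a gene ending 8 kb before that fails
        ann = GenomeAnnotation(
            chroms={"chr1": make_chrom()},
            genes=[gene("edge", 975_000, 982_000), gene("deep", 500_000, 505_000)],
            tes=[],
        )
        assert [g.gene_id for g in select_analysis_genes(ann)] == ["deep"]

    def test_exclusion_list(self):
        ann = GenomeAnnotation(
            chroms={"chr1": make_chrom()},
            genes=[gene("a", 500_000, 505_000), gene("b", 600_000, 605_000)],
            tes=[],
        )
        assert [g.gene_id for g in select_analysis_genes(ann, exclude_ids=["a"])] == ["b"]


class TestDistanceGeometry:
    g = gene("g", 100_000, 105_000)

    @pytest.mark.parametrize(
        "te_span, expected",
        [
            ((105_500, 106_000), "within_1kb"),   # 500 bp downstream
            ((106_500, 107_000), "1-2kb"),        # 1.5 kb downstream
            ((99_000, 100_000), "within_1kb"),    # abutting: distance 0
            ((106_000, 108_000), "within_1kb"),   # exactly 1,000 bp: (0,1000] bin
            ((107_000, 108_000), "1-2kb"),        # exactly 2,000 bp: (1000,2000]
            ((112_000, 113_000), "5-10kb"),
        ],
    )
    def test_distance_category_bins(self, te_span, expected):
        assert distance_category(self.g, [te("t", *te_span)]) == expected

    def test_no_te_within_10kb(self):
        assert distance_category(self.g, [te("far", 200_000, 201_000)]) == "none_within_10kb"

    def test_nearest_te_minimal_and_tie_exclusion(self):
        near = te("near", 105_300, 105_800)      # 300 bp
        far = te("far", 109_000, 110_000)        # 4,000 bp
        best, d, tie = nearest_te(self.g, [near, far])
        assert best.te_id == "near" and d == 300 and not tie
        left = te("left", 99_000, 99_300)        # 700 bp upstream
        right = te("right", 105_700, 106_000)    # 700 bp downstream
        best, d, tie = nearest_te(self.g, [left, right])
        assert best is None and d == 700 and tie

    def test_nearest_te_intronic_distance_zero(self):
        g = gene("gi", 100_000, 110_000, [(100_000, 103_000), (107_000, 110_000)])
        t = te("tin", 104_000, 105_000)
        best, d, tie = nearest_te(g, [t])
        assert best.te_id == "tin" and d == 0 and not tie

    def test_te_counts_closest_window_rule(self):
        # TE spanning 1.8-2.3 kb from the gene: counted in 1-2kb only
        t = te("span", 105_000 + 1_800, 105_000 + 2_300)
        counts = te_counts_by_bin(self.g, [t])
        assert counts["1-2kb"] == 1 and sum(counts.values()) == 1

    def test_te_counts_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            tes = []
            for i in range(5):
                start = int(rng.integers(85_000, 120_000))
                tes.append(te(f"t{i}", start, start + int(rng.integers(100, 3_000))))
            counts = te_counts_by_bin(self.g, tes)
            # oracle: classify each TE independently by its minimal edge distance
            expected = {"in_gene": 0, "0-1kb": 0, "1-2kb": 0, "2-5kb": 0, "5-10kb": 0}
            for t in tes:
                d, overlap = te_gene_distance(self.g, t)
                if overlap:
                    expected["in_gene"] += 1
                elif d <= 1_000:
                    expected["0-1kb"] += 1
                elif d <= 2_000:
                    expected["1-2kb"] += 1
                elif d <= 5_000:
                    expected["2-5kb"] += 1
                elif d <= 10_000:
                    expected["5-10kb"] += 1
            assert counts == expected

    def test_category_agrees_with_innermost_bin_and_conservation(self):
        rng = np.random.default_rng(7)
        bin_to_cat = {
            "in_gene": "in_gene", "0-1kb": "within_1kb", "1-2kb": "1-2kb",
            "2-5kb": "2-5kb", "5-10kb": "5-10kb",
        }
        order = ["in_gene", "0-1kb", "1-2kb", "2-5kb", "5-10kb"]
        for _ in range(50):
            tes = []
            for i in range(int(rng.integers(0, 6))):
                start = int(rng.integers(85_000, 125_000))
                tes.append(te(f"t{i}", start, start + int(rng.integers(50, 2_000))))
            counts = te_counts_by_bin(self.g, tes)
            cat = distance_category(self.g, tes)
            inner = next((b for b in order if counts[b] > 0), None)
            assert cat == (bin_to_cat[inner] if inner else "none_within_10kb")
            # every TE within 10 kb is in exactly one bin
            within = sum(
                1 for t in tes
                if te_gene_distance(self.g, t)[1] or te_gene_distance(self.g, t)[0] <= 10_000
            )
            assert sum(counts.values()) == within
            # nearest distance is a lower bound for all binned TEs
            best, d, _ = nearest_te(self.g, tes)
            if d is not None:
                dists = [
                    0 if te_gene_distance(self.g, t)[1] else te_gene_distance(self.g, t)[0]
                    for t in tes
                    if te_gene_distance(self.g, t)[1] or te_gene_distance(self.g, t)[0] <= 10_000
                ]
                assert d == min(dists)

    def test_distance_tertiles_equal_thirds(self):
        labels = distance_tertiles([10, 20, 30, 40, 50, 60])
        assert list(labels) == [0, 0, 1, 1, 2, 2]
        # cuts follow the data, not fixed bp values
        labels = distance_tertiles([5_000, 1, 2, 9_000, 3, 6_000])
        assert labels[1] == labels[2] == 0      # two smallest -> short
        assert labels[4] == labels[0] == 1      # rank-based, not bp-based
        assert labels[3] == labels[5] == 2


class TestLocalContext:
    recomb = pd.DataFrame(
        {"chrom": ["chr1"] * 3, "pos": [0, 100_000, 200_000], "rate": [2.0, 4.0, 1.0]}
    )

    def test_lone_gene_counts_itself(self):
        g = gene("solo", 50_000, 52_000)
        density, _ = local_context(g, [g], self.recomb)
        assert density == 1

    def test_linear_interpolation_midway(self):
        g = gene("mid", 49_000, 51_000)  # midpoint 50,000 between rates 2 and 4
        _, rate = local_context(g, [g], self.recomb)
        assert rate == pytest.approx(3.0)

    def test_rate_clamped_beyond_map(self):
        g = gene("end", 400_000, 402_000)
        _, rate = local_context(g, [g], self.recomb)
        assert rate == pytest.approx(1.0)

    def test_empty_map_raises(self):
        g = gene("x", 50_000, 52_000)
        other_chrom = self.recomb.assign(chrom="chr9")
        with pytest.raises(ValueError):
            local_context(g, [g], other_chrom)


class TestIntergenicMask:
    def test_mask_merges_and_queries(self):
        ann = GenomeAnnotation(
            chroms={"chr1": make_chrom()},
            genes=[gene("g", 50_000, 55_000)],
            tes=[te("t", 54_000, 58_000), te("t2", 80_000, 81_000)],
        )
        mask = intergenic_intervals(ann)
        assert is_intergenic(mask, "chr1", 60_000, 70_000)
        assert not is_intergenic(mask, "chr1", 57_999, 60_000)
        assert not is_intergenic(mask, "chr1", 40_000, 50_001)
        assert is_intergenic(mask, "chr1", 58_000, 80_000)
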