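import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gdnaclean as gd
from gdnaclean import intervals
from gdnaclean.annotation import AnnotationError, RegionSet


class TestLoadGeneModels:
    def test_toy_gtf_parses_genes_exons_and_biotypes(self, toy_models):
        assert sorted(toy_models.gene_ids) == ["G1", "G2", "G3"]
        assert toy_models["G1"].n_exons == 2
        assert toy_models["G2"].n_exons == 1
        assert {g.gene_id: g.biotype for g in toy_models.genes} == {
            "G1": "protein_coding",
            "G2": "rRNA",
            "G3": "lincRNA",
        }
        assert toy_models["G2"].strand == "-"

    def test_chrom_absent_from_fasta_index_is_an_error(self, toy_files):
        with pytest.raises(AnnotationError, match="chr1"):
            gd.load_gene_models(toy_files["gtf"], {"chrX": 1000})

    def test_exon_without_gene_id_is_a_parse_error(self, tmp_path):
        bad = tmp_path / "bad.gtf"
        bad.write_text('chr1\tx\texon\t1\t100\t.\t+\t.\ttranscript_id "T1";\n')
        with pytest.raises(AnnotationError):
            gd.load_gene_models(bad, {"chr1": 1000})

    def test_union_exon_length_merges_overlaps(self, toy_models):
        lengths = toy_models.union_exon_lengths()
        assert lengths["G1"] == 200
        assert lengths["G3"] == 150


class TestFeatureCatalog:
    def test_intergenic_is_the_complement_of_gene_spans(self, toy_models):
        cat = gd.build_feature_catalog(toy_models, organellar_chroms=("MT",))
        ig = cat["intergenic"].regions
        got = set(zip(ig["start"], ig["end"]))
        # gene spans: [1,300], [401,500], [601,800] on a 1000 bp chromosome
        assert got == {(301, 400), (501, 600), (801, 1000)}

    def test_introns_are_span_minus_exons(self, toy_models):
        cat = gd.build_feature_catalog(toy_models, organellar_chroms=("MT",))
        intr = cat["intron"].regions
        got = set(zip(intr["start"], intr["end"]))
        assert got == {(101, 200), (651, 700)}

    def test_overlapping_genes_collapse_into_one_exon_region(self):
        models = gd.GeneModelSet(
            genes=[
                gd.Gene("A", "c", "+", "protein_coding", ((1, 100),)),
                gd.Gene("B", "c", "-", "protein_coding", ((51, 150),)),
            ],
            chrom_lengths={"c": 200},
        )
        cat = gd.build_feature_catalog(models, organellar_chroms=())
        ex = cat["collapsed_exon"].regions
        assert list(zip(ex["start"], ex["end"])) == [(1, 150)]
        # brute-force base-wise union
        covered = np.zeros(200, dtype=bool)
        covered[0:100] = True
        covered[50:150] = True
        assert cat["collapsed_exon"].lengths.sum() == covered.sum()

    def test_rrna_catalog_follows_biotype(self, toy_models):
        cat = gd.build_feature_catalog(toy_models, organellar_chroms=("MT",))
        rr = cat["rRNA_exon"].regions
        assert list(zip(rr["start"], rr["end"])) == [(401, 500)]

    def test_missing_organellar_chrom_is_an_error(self, toy_models):
        with pytest.raises(AnnotationError, match="chrM"):
            gd.build_feature_catalog(toy_models, organellar_chroms=("chrM",))

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_covers_each_chromosome_exactly(self, seed):
        ref = gd.make_reference(seed=seed, n_chroms=1, chrom_length=150_000, n_genes=10, window=0)
        cat = ref.catalog
        L = ref.chrom_lengths["chr1"]
        total = sum(
            cat[c].regions.query("chrom == 'chr1'").eval("end - start + 1").sum()
            for c in ("collapsed_exon", "intron", "intergenic")
        )
        assert total == L
        # pairwise overlap by sweep over all breakpoints
        spans = []
        for c in ("collapsed_exon", "intron", "intergenic"):
            df = cat[c].regions.query("chrom == 'chr1'")
            spans.extend(zip(df["start"], df["end"]))
        spans.sort()
        for (_s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            assert s2 > e1


class TestGc:
    def test_simple_sequences(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c\nATGCNNNN\n")
        rs = RegionSet(
            "custom",
            pd.DataFrame(
                [("r1", "c", 1, 4, "."), ("r2", "c", 5, 8, ".")],
                columns=["region_id", "chrom", "start", "end", "strand"],
            ),
        )
        prof = gd.compute_gc(rs, fa)
        assert prof.series["r1"] == 0.5
        assert np.isnan(prof.series["r2"])  # undefined: no ACGT bases

    def test_gene_gc_over_union_exons(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c\nATGCCCAAAA\n")
        models = gd.GeneModelSet(
            genes=[gd.Gene("g", "c", "+", "x", ((1, 3), (4, 6)))],
            chrom_lengths={"c": 10},
        )
        prof = gd.compute_gc(models, fa)
        assert prof.series["g"] == pytest.approx(4 / 6)  # "ATG" + "CCC"

    def test_interval_beyond_sequence_end_is_an_error(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c\nACGT\n")
        rs = RegionSet(
            "custom",
            pd.DataFrame(
                [("r", "c", 2, 9, ".")],
                columns=["region_id", "chrom", "start", "end", "strand"],
            ),
        )
        with pytest.raises(AnnotationError, match="beyond"):
            gd.compute_gc(rs, fa)

    def test_matches_bruteforce_on_random_regions(self, toy_files):
        rng = np.random.default_rng(9)
        seq = toy_files["chr1"]
        rows = []
        for i in range(100):
            s = int(rng.integers(1, 900))
            e = int(s + rng.integers(1, 100))
            rows.append((f"r{i}", "chr1", s, e, "."))
        df = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "strand"])
        df = df.drop_duplicates(["chrom", "start", "end"])  # RegionSet forbids overlap
        # brute force per region; use a non-overlapping subset
        keep, last_end = [], {}
        for row in df.sort_values("start").itertuples():
            if last_end.get(row.chrom, 0) < row.start:
                keep.append(row)
                last_end[row.chrom] = row.end
        rs = RegionSet(
            "custom",
            pd.DataFrame(
                [(r.region_id, r.chrom, r.start, r.end, r.strand) for r in keep],
                columns=["region_id", "chrom", "start", "end", "strand"],
            ),
        )
        prof = gd.compute_gc(rs, toy_files["fasta"]).series
        for r in keep:
            sub = seq[r.start - 1 : r.end]
            expected = (sub.count("G") + sub.count("C")) / len(sub)
            assert prof[r.region_id] == pytest.approx(expected)


class TestSaf:
    def test_round_trip_identity(self, toy_models, tmp_path):
        cat = gd.build_feature_catalog(toy_models, organellar_chroms=("MT",))
        p = tmp_path / "x.saf"
        gd.write_saf(cat["intergenic"], p)
        back = gd.read_saf(p, category="intergenic")
        pd.testing.assert_frame_equal(back.regions, cat["intergenic"].regions)

    def test_single_row_parse(self, tmp_path):
        p = tmp_path / "one.saf"
        p.write_text("GeneID\tChr\tStart\tEnd\tStrand\nR1\tchr1\t1\t200\t+\n")
        rs = gd.read_saf(p)
        r = rs.regions.iloc[0]
        assert (r["region_id"], r["chrom"], r["start"], r["end"], r["strand"]) == (
            "R1", "chr1", 1, 200, "+",
        )

    def test_three_region_lengths(self, tmp_path):
        p = tmp_path / "three.saf"
        p.write_text(
            "GeneID\tChr\tStart\tEnd\tStrand\n"
            "A\tc\t1\t200\t.\nB\tc\t301\t900\t.\nC\tc\t1001\t1100\t.\n"
        )
        assert sorted(gd.read_saf(p).lengths) == [100, 200, 600]

    def test_malformed_column_count_names_the_line(self, tmp_path):
        p = tmp_path / "bad.saf"
        p.write_text("GeneID\tChr\tStart\tEnd\tStrand\nA\tc\t1\t200\t.\nB\tc\t300\n")
        with pytest.raises(AnnotationError, match=":3"):
            gd.read_saf(p)

    def test_tiling_preserves_total_length(self, toy_models):
        cat = gd.build_feature_catalog(toy_models, organellar_chroms=("MT",))
        tiled = gd.tile_regions(cat["intergenic"], 70)
        assert tiled.lengths.sum() == cat["intergenic"].lengths.sum()
        assert tiled.lengths.max() <= 70


@settings(deadline=None, max_examples=50)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 80)), min_size=1, max_size=30
    ),
    length=st.integers(600, 1000),
)
def test_merge_and_complement_partition_the_chromosome(data, length):
    starts = np.array([s for s, _ in data])
    ends = np.array([min(s + l, length) for s, l in data])
    ms, me = intervals.merge(starts, ends)
    cs, ce = intervals.complement(starts, ends, length)
    assert (me - ms).sum() + (ce - cs).sum() == length
    both_s = np.concatenate([ms, cs])
    both_e = np.concatenate([me, ce])
    order = np.argsort(both_s)
    assert (both_s[order][1:] >= both_e[order][:-1]).all()
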