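"""Annotation layer: dialect parsing, coordinate conventions, overlap index,
precursor-cluster assignment and genome-abundance composition."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tepi.annotations import (
    AnnotationError,
    FeatureSet,
    GenomicInterval,
    PiRNACluster,
    RepeatFeature,
    assign_precursors_to_clusters,
    expected_composition,
    load_gene_annotation,
    load_pirna_annotations,
    load_repeat_annotation,
)

RM_OUT = """\
   SW   perc perc perc  query     position in query    matching repeat
score   div. del. ins.  sequence  begin end (left)     repeat class/family begin end (left) ID

 1000   10.0  0.5  0.5  chr2L     100   180  (9000) +  Gypsy-like  LTR/Gypsy      1  81 (0)   1
  500   12.0  0.1  0.1  chr2L     500   620  (8000) C  Jockey-el   LINE/Jockey    1 121 (0)   2
  200    5.0  0.0  0.0  chr2R     10    90   (9900) +  (AT)n       Simple_repeat  1  81 (0)   3
"""

BED_EQUIV = (
    "chr2L\t99\t180\tGypsy-like#LTR/Gypsy\t0\t+\n"
    "chr2L\t499\t620\tJockey-el#LINE/Jockey\t0\t-\n"
    "chr2R\t9\t90\t(AT)n#Simple_repeat\t0\t+\n"
)

GTF_EQUIV = (
    'chr2L\trm\trepeat\t100\t180\t.\t+\t.\trepeat_name "Gypsy-like"; order "LTR"; family "Gypsy";\n'
    'chr2L\trm\trepeat\t500\t620\t.\t-\t.\trepeat_name "Jockey-el"; order "LINE"; family "Jockey";\n'
    'chr2R\trm\trepeat\t10\t90\t.\t+\t.\trepeat_name "(AT)n"; order "Simple_repeat"; family "Simple_repeat";\n'
)


class TestGenomicInterval:
    def test_rejects_degenerate_coordinates(self):
        with pytest.raises(AnnotationError):
            GenomicInterval("chrA", 10, 10)
        with pytest.raises(AnnotationError):
            GenomicInterval("chrA", -1, 5)
        with pytest.raises(AnnotationError):
            GenomicInterval("", 0, 5)

    def test_overlap_length(self):
        a = GenomicInterval("chrA", 0, 100)
        assert a.overlap_length(GenomicInterval("chrA", 50, 150)) == 50
        assert a.overlap_length(GenomicInterval("chrB", 50, 150)) == 0
        assert a.overlap_length(GenomicInterval("chrA", 100, 150)) == 0


class TestRepeatLoading:
    def test_repeatmasker_out_coordinates_and_classes(self, tmp_path):
        path = tmp_path / "rm.out"
        path.write_text(RM_OUT)
        fs = load_repeat_annotation(path, "repeatmasker_out")
        assert len(fs) == 3
        gypsy = fs.features[0]
        # 1-based inclusive 100..180 becomes 0-based half-open [99, 180)
        assert (gypsy.interval.start, gypsy.interval.end) == (99, 180)
        assert (gypsy.order, gypsy.family) == ("LTR", "Gypsy")
        assert fs.features[1].interval.strand == "-"  # RepeatMasker 'C'
        simple = fs.features[2]
        assert (simple.order, simple.family) == ("Simple_repeat", "Simple_repeat")

    def test_dialect_equivalence(self, tmp_path):
        (tmp_path / "rm.out").write_text(RM_OUT)
        (tmp_path / "rm.bed").write_text(BED_EQUIV)
        (tmp_path / "rm.gtf").write_text(GTF_EQUIV)
        loaded = {
            dialect: load_repeat_annotation(tmp_path / name, dialect)
            for dialect, name in [
                ("repeatmasker_out", "rm.out"), ("bed", "rm.bed"), ("gtf", "rm.gtf")
            ]
        }
        reference = [
            (f.interval, f.repeat_name, f.order, f.family)
            for f in loaded["repeatmasker_out"]
        ]
        for dialect in ("bed", "gtf"):
            assert [
                (f.interval, f.repeat_name, f.order, f.family) for f in loaded[dialect]
            ] == reference

    def test_malformed_coordinates_reported_with_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr2L\t200\t100\tx#LTR/Gypsy\t0\t+\n")
        with pytest.raises(AnnotationError, match="line 1"):
            load_repeat_annotation(path, "bed")

    def test_unknown_dialect(self, tmp_path):
        path = tmp_path / "x.bed"
        path.write_text(BED_EQUIV)
        with pytest.raises(AnnotationError, match="dialect"):
            load_repeat_annotation(path, "vcf")

    def test_bed_round_trip(self, tmp_path, small_bundle):
        out = tmp_path / "repeats.bed"
        small_bundle.repeats.to_bed(out)
        reloaded = load_repeat_annotation(out, "bed")
        assert [f.feature_id for f in reloaded] == small_bundle.repeats.feature_ids
        assert [f.interval for f in reloaded] == [f.interval for f in small_bundle.repeats]
        assert [(f.order, f.family) for f in reloaded] == [
            (f.order, f.family) for f in small_bundle.repeats
        ]


class TestGeneLoading:
    GTF = (
        'chrA\tx\tgene\t1001\t2000\t.\t+\t.\tgene_id "g1";\n'
        'chrA\tx\texon\t1001\t1200\t.\t+\t.\tgene_id "g1";\n'
        'chrA\tx\texon\t1801\t2000\t.\t+\t.\tgene_id "g1";\n'
    )

    def test_gtf_gene_with_exons(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text(self.GTF)
        fs = load_gene_annotation(path, "gtf")
        gene = fs["g1"]
        assert (gene.interval.start, gene.interval.end) == (1000, 2000)
        assert len(gene.exons) == 2
        assert gene.exons[0].start == 1000

    def test_gff3_parent_attribute(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "chrA\tx\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
            "chrA\tx\texon\t1001\t1200\t.\t+\t.\tParent=g1\n"
        )
        fs = load_gene_annotation(path, "gff3")
        assert len(fs["g1"].exons) == 1

    def test_span_only_source_allowed(self, tmp_path):
        path = tmp_path / "genes.gtf"
        path.write_text('chrA\tx\tgene\t1001\t2000\t.\t+\t.\tgene_id "g1";\n')
        fs = load_gene_annotation(path, "gtf")
        assert fs["g1"].exons == ()

    @pytest.mark.parametrize(
        "extra, message",
        [
            ('chrA\tx\texon\t100\t200\t.\t+\t.\tgene_id "orphan";\n', "orphan"),
            ('chrA\tx\texon\t2500\t2600\t.\t+\t.\tgene_id "g1";\n', "g1"),
            ('chrA\tx\tgene\t3001\t4000\t.\t+\t.\tgene_id "g1";\n', "duplicated"),
        ],
        ids=["exon-without-gene", "exon-outside-span", "duplicate-gene-id"],
    )
    def test_invariant_violations(self, tmp_path, extra, message):
        path = tmp_path / "genes.gtf"
        path.write_text(self.GTF + extra)
        with pytest.raises(AnnotationError, match=message):
            load_gene_annotation(path, "gtf")


class TestPiRNALoading:
    def test_cluster_name_dialect(self, tmp_path):
        prec = tmp_path / "prec.bed"
        prec.write_text("chr2R\t100\t300\tp1\t0\t+\n")
        clus = tmp_path / "clus.bed"
        clus.write_text("chr2R\t0\t100000\t42AB|dual\t0\t.\nchr2L\t0\t50000\t20A|uni\t0\t.\n")
        precursors, clusters = load_pirna_annotations(prec, clus)
        assert [c.cluster_id for c in clusters] == ["42AB", "20A"]
        assert [c.strand_mode for c in clusters] == ["dual", "uni"]
        assert precursors.features[0].cluster_id is None

    def test_bad_strand_mode_token(self, tmp_path):
        prec = tmp_path / "p.bed"
        prec.write_text("")
        clus = tmp_path / "c.bed"
        clus.write_text("chr2R\t0\t1000\t42AB|both\t0\t.\n")
        with pytest.raises(AnnotationError):
            load_pirna_annotations(prec, clus)

    def test_empty_precursor_file(self, tmp_path):
        prec = tmp_path / "p.bed"
        prec.write_text("")
        clus = tmp_path / "c.bed"
        clus.write_text("chr2R\t0\t1000\t42AB|dual\t0\t.\n")
        precursors, _ = load_pirna_annotations(prec, clus)
        assert len(precursors) == 0

    def test_nested_clusters_rejected(self, tmp_path):
        prec = tmp_path / "p.bed"
        prec.write_text("")
        clus = tmp_path / "c.bed"
        clus.write_text("chr2R\t0\t1000\tA|dual\t0\t.\nchr2R\t100\t900\tB|uni\t0\t.\n")
        with pytest.raises(AnnotationError, match="nested"):
            load_pirna_annotations(prec, clus)


def _cluster(cid, chrom, start, end, mode="dual"):
    return PiRNACluster(cid, GenomicInterval(chrom, start, end), mode)


def _precursor_set(intervals):
    from tepi.annotations import PiRNAPrecursor

    return FeatureSet(
        [PiRNAPrecursor(f"p{i}", iv) for i, iv in enumerate(intervals)], "precursor"
    )


class TestPrecursorAssignment:
    def test_contained_assigned_and_partial_not(self):
        precs = _precursor_set(
            [GenomicInterval("c", 10, 20), GenomicInterval("c", 95, 115)]
        )
        out = assign_precursors_to_clusters(precs, [_cluster("X", "c", 0, 100)])
        # [10,20) fully inside; [95,115) overlaps 5/20 = 0.25 < 0.5
        assert out.features[0].cluster_id == "X"
        assert out.features[1].cluster_id is None

    def test_tie_breaks_to_lexicographically_smaller(self):
        precs = _precursor_set([GenomicInterval("c", 92, 108)])
        clusters = [_cluster("beta", "c", 0, 100), _cluster("alpha", "c", 100, 200)]
        out = assign_precursors_to_clusters(precs, clusters, min_overlap_fraction=0.4)
        assert out.features[0].cluster_id == "alpha"

    def test_largest_overlap_wins(self):
        precs = _precursor_set([GenomicInterval("c", 90, 110)])
        clusters = [_cluster("A", "c", 0, 102), _cluster("B", "c", 102, 200)]
        out = assign_precursors_to_clusters(precs, clusters, min_overlap_fraction=0.1)
        assert out.features[0].cluster_id == "A"


def _repeat(fid, order, family, length, chrom="c", start=0):
    return RepeatFeature(
        GenomicInterval(chrom, start, start + length), f"{family}-el", family, order, fid
    )


class TestExpectedComposition:
    def test_element_count_weighting(self):
        fs = FeatureSet(
            [
                _repeat("a", "LTR", "Gypsy", 300, start=0),
                _repeat("b", "LTR", "Pao", 300, start=1000),
                _repeat("c", "LINE", "Jockey", 100, start=2000),
                _repeat("d", "LINE", "Jockey", 100, start=3000),
            ],
            "repeat",
        )
        assert expected_composition(fs, "order", "element_count") == {
            "LINE": 0.5, "LTR": 0.5,
        }

    def test_base_pair_weighting(self):
        fs = FeatureSet(
            [
                _repeat("a", "LTR", "Gypsy", 300, start=0),
                _repeat("b", "LINE", "Jockey", 100, start=1000),
            ],
            "repeat",
        )
        assert expected_composition(fs, "order", "base_pairs") == {"LINE": 0.25, "LTR": 0.75}

    def test_single_class_and_empty(self):
        fs = FeatureSet([_repeat("a", "LTR", "Gypsy", 300)], "repeat")
        assert expected_composition(fs) == {"LTR": 1.0}
        with pytest.raises(AnnotationError):
            expected_composition(FeatureSet([], "repeat"))

    def test_fractions_sum_to_one_and_order_invariant(self, small_bundle):
        fs = small_bundle.repeats
        comp = expected_composition(fs, "family")
        assert abs(sum(comp.values()) - 1.0) < 1e-9
        reversed_fs = FeatureSet(list(fs)[::-1], "repeat")
        assert expected_composition(reversed_fs, "family") == comp


@settings(max_examples=50, deadline=None)
@given(
    intervals=st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 50)), min_size=1, max_size=200
    ),
    query=st.tuples(st.integers(0, 500), st.integers(1, 60)),
)
def test_overlap_index_matches_linear_scan(intervals, query):
    """The interval-tree index returns exactly the brute-force overlap set."""
    feats = [
        _repeat(f"r{i}", "LTR", "Gypsy", length, start=start)
        for i, (start, length) in enumerate(intervals)
    ]
    fs = FeatureSet(feats, "repeat")
    q_start, q_len = query
    q_end = q_start + q_len
    hits = {f.feature_id for f in fs.query("c", q_start, q_end)}
    brute = {
        f.feature_id
        for f in feats
        if f.interval.start < q_end and f.interval.end > q_start
    }
    assert hits == brute
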