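"""File format parsing, coordinate normalization and round trips."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvdrive.cnv_events import Segment, segments_to_events
from cnvdrive.diffexpr import DegRecord
from cnvdrive.errors import DataError
from cnvdrive.formats_io import (
    INTERNAL_DIALECT,
    SEG_DIALECT,
    GeneModel,
    SegmentFileDialect,
    normalize_chromosome,
    read_expression,
    read_gene_models,
    read_gene_sets,
    read_segments,
    write_circos_tracks,
    write_segments,
)

from conftest import make_segment


class TestReadSegments:
    def test_one_based_inclusive_normalized(self, tmp_path):
        seg = tmp_path / "toy.seg"
        seg.write_text(
            "sample\tchrom\tstart\tend\tnum.mark\tseg.mean\n"
            "s1\t1\t1001\t2000\t10\t0.5\n"
            "s1\tchr2\t1\t1500\t5\t-0.3\n"
            "s2\t3\t5001\t9000\t7\t0.0\n"
        )
        segments = read_segments(seg, SEG_DIALECT, group="case")
        assert len(segments) == 3
        first = segments[0]
        assert (first.start, first.end, first.length) == (1000, 2000, 1000)
        assert segments[1].chromosome == 2  # 'chr2' accepted
        assert segments[1].start == 0

    def test_sex_chromosome_rejected(self, tmp_path):
        seg = tmp_path / "x.seg"
        seg.write_text("sample\tc\ts\te\tn\tm\ns1\tX\t1\t2000\t5\t0.5\n")
        with pytest.raises(DataError, match="X"):
            read_segments(seg)

    def test_malformed_row_names_line(self, tmp_path):
        seg = tmp_path / "bad.seg"
        seg.write_text("sample\tc\ts\te\tn\tm\ns1\t1\toops\t2000\t5\t0.5\n")
        with pytest.raises(DataError, match=":2"):
            read_segments(seg)

    def test_missing_segment_mean_becomes_nan(self, tmp_path):
        seg = tmp_path / "na.seg"
        seg.write_text("sample\tc\ts\te\tn\tm\ns1\t1\t1\t2000\t5\tNA\n")
        (segment,) = read_segments(seg)
        assert math.isnan(segment.segment_mean)

    @pytest.mark.parametrize(
        "one_based,end_inclusive,start,end,expected",
        [
            (True, True, 1001, 2000, (1000, 2000)),
            (True, False, 1001, 2001, (1000, 2000)),
            (False, False, 1000, 2000, (1000, 2000)),
            (False, True, 1000, 1999, (1000, 2000)),
        ],
    )
    def test_dialect_conventions_agree(self, one_based, end_inclusive, start, end,
                                       expected):
        dialect = SegmentFileDialect(one_based=one_based, end_inclusive=end_inclusive)
        assert dialect.to_internal(start, end) == expected

    def test_normalization_idempotent(self):
        # internal coordinates pass through the internal dialect unchanged
        assert INTERNAL_DIALECT.to_internal(1000, 2000) == (1000, 2000)


segments_strategy = st.lists(
    st.builds(
        Segment,
        sample=st.sampled_from(["s1", "s2", "s3"]),
        group=st.just("case"),
        chromosome=st.integers(1, 22),
        start=st.integers(0, 10_000),
        end=st.integers(10_001, 100_000),
        segment_mean=st.floats(-3, 3, allow_nan=False, width=32),
    ),
    max_size=20,
)


class TestSegmentRoundTrip:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(segments=segments_strategy)
    def test_write_read_identity(self, tmp_path_factory, segments):
        path = tmp_path_factory.mktemp("seg") / "rt.seg"
        write_segments(path, segments)
        back = read_segments(path, INTERNAL_DIALECT, group="case")
        assert back == segments

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(segments=segments_strategy)
    def test_write_read_write_byte_identical(self, tmp_path_factory, segments):
        base = tmp_path_factory.mktemp("seg")
        first, second = base / "a.seg", base / "b.seg"
        write_segments(first, segments)
        write_segments(second, read_segments(first, INTERNAL_DIALECT, group="case"))
        assert first.read_bytes() == second.read_bytes()


class TestExpressionIO:
    def test_round_trip_and_groups(self, tmp_path, toy_expression):
        from cnvdrive.formats_io import write_expression

        expr, groups = tmp_path / "e.tsv", tmp_path / "g.tsv"
        write_expression(toy_expression, expr, groups)
        back = read_expression(expr, groups)
        assert back.genes == toy_expression.genes
        assert back.tumor_samples == ["t1", "t2"]
        assert back.normal_samples == ["n1", "n2"]
        assert back.values.equals(toy_expression.values)

    def test_duplicate_gene_rejected(self, tmp_path):
        expr = tmp_path / "e.tsv"
        expr.write_text("gene\ts1\ts2\nA\t1\t2\nA\t3\t4\n")
        groups = tmp_path / "g.tsv"
        groups.write_text("sample\tgroup\ns1\ttumor\ns2\tnormal\n")
        with pytest.raises(DataError, match="duplicated gene"):
            read_expression(expr, groups)

    def test_empty_group_rejected(self, tmp_path):
        expr = tmp_path / "e.tsv"
        expr.write_text("gene\ts1\ts2\nA\t1\t2\n")
        groups = tmp_path / "g.tsv"
        groups.write_text("sample\tgroup\ns1\ttumor\ns2\ttumor\n")
        with pytest.raises(DataError, match="non-empty"):
            read_expression(expr, groups)


class TestGeneModelIO:
    def test_bed_like_line(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t100\t500\tGENE1\t+\n")
        (model,) = read_gene_models(bed)
        assert model == GeneModel("GENE1", 1, 100, 500, "+")

    def test_duplicate_symbol_rejected(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t100\t500\tGENE1\t+\n2\t100\t500\tGENE1\t-\n")
        with pytest.raises(DataError, match="duplicate"):
            read_gene_models(bed)


class TestGeneSetIO:
    def test_gmt_parses(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("term1\tdesc\tGeneA\tgeneB\n")
        sets = read_gene_sets(gmt)
        assert sets["term1"].genes == frozenset({"GENEA", "GENEB"})

    def test_empty_set_rejected(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("term1\tdesc\t\n")
        with pytest.raises(DataError):
            read_gene_sets(gmt)


class TestCircosTracks:
    def test_track_rows_match_event_counts(self, tmp_path):
        segments = [
            make_segment("a", "case", 1, 0, 10_000, 0.6),
            make_segment("b", "case", 1, 0, 10_000, 0.6),
            make_segment("c", "control", 2, 0, 5_000, -0.6),
        ]
        events = segments_to_events(segments)
        degs = [DegRecord("GENE1", 2.0, "up")]
        models = {"GENE1": GeneModel("GENE1", 1, 100, 500)}
        tracks = write_circos_tracks(events, degs, tmp_path / "circos", models)
        counts = {
            name: len(path.read_text().splitlines()) for name, path in tracks.items()
        }
        assert counts["cnv_case_duplication.txt"] == 2
        assert counts["cnv_control_deletion.txt"] == 1
        assert counts["cnv_case_deletion.txt"] == 0
        assert counts["cnv_control_duplication.txt"] == 0
        assert counts["degs.txt"] == 1

    def test_empty_input_no_crash(self, tmp_path):
        tracks = write_circos_tracks([], [], tmp_path / "circos")
        assert all(p.read_text() == "" for p in tracks.values())


def test_normalize_chromosome_accepts_both_spellings():
    assert normalize_chromosome("chr7") == normalize_chromosome("7") == 7
    with pytest.raises(DataError, match="MT"):
        normalize_chromosome("MT")
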