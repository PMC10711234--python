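"""Report writers: CSV/TSV contracts, HTML integrity, figures."""

import pandas as pd
import pytest

from rsrnakit.classify import RsRNARecord
from rsrnakit.report import (
    ANNOTATION_COLUMNS,
    build_summary,
    make_figures,
    read_annotation_csv,
    write_abundance_summary,
    write_annotation_csv,
    write_class_counts,
    write_html_report,
)


def _rec(category="rRF-5", gene_id="g1", rpm=100.0, seq="ACGUACGUACGUACGUA",
         count=10, seq_count=8, gene_start=1, gene_end=17, rrna_type="18S",
         origin="nuclear", genomic_start=1001, genomic_end=1017):
    return RsRNARecord(
        category=category, gene_id=gene_id,
        rrna_info=f"{gene_id}|chr1:1001-2808(+)|{rrna_type}",
        rrna_type=rrna_type, origin=origin, gene_start=gene_start,
        gene_end=gene_end, sequence=seq, genomic_start=genomic_start,
        genomic_end=genomic_end, difference=0, rpm=rpm,
        seq_count=seq_count, count=count,
    )


class TestAnnotationCsv:
    def test_empty_records_header_only(self, tmp_path):
        path = write_annotation_csv([], tmp_path / "a.csv")
        lines = path.read_text().splitlines()
        assert lines == [",".join(ANNOTATION_COLUMNS)]

    def test_single_record_field_count(self, tmp_path):
        path = write_annotation_csv([_rec()], tmp_path / "a.csv")
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert len(lines[1].split(",")) == 12

    def test_column_order_is_fixed(self, tmp_path):
        path = write_annotation_csv([_rec()], tmp_path / "a.csv")
        frame = read_annotation_csv(path)
        assert list(frame.columns) == ANNOTATION_COLUMNS == [
            "Category", "rRNA_info", "Gene_Start", "Gene End", "Sequence",
            "Length", "Genomic Start", "Genomic End", "Difference", "RPM",
            "Seq_count", "count",
        ]

    def test_round_trip(self, tmp_path):
        records = [
            _rec(rpm=12.345, count=25, seq_count=20),
            _rec(category="rRF-i", gene_start=50, gene_end=70,
                 seq="G" * 21, rpm=10.0, count=2, seq_count=2),
        ]
        path = write_annotation_csv(records, tmp_path / "a.csv")
        frame = read_annotation_csv(path)
        for rec, (_, row) in zip(records, frame.iterrows()):
            assert row["Category"] == rec.category
            assert row["Gene_Start"] == rec.gene_start
            assert row["Gene End"] == rec.gene_end
            assert row["Sequence"] == rec.sequence
            assert row["Length"] == rec.length
            assert row["RPM"] == round(rec.rpm, 2)
            assert row["count"] == rec.count


class TestClassCounts:
    def test_counts_and_zero_rows(self, tmp_path):
        records = [_rec()] * 3 + [_rec(category="rRF-i")] * 2
        path = write_class_counts(records, tmp_path / "c.tsv")
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert rows == [["rRF-5", "3"], ["rRF-3", "0"], ["rRF-i", "2"]]

    def test_empty_gives_three_zero_rows(self, tmp_path):
        path = write_class_counts([], tmp_path / "c.tsv")
        rows = [line.split("\t") for line in path.read_text().splitlines()]
        assert [r[1] for r in rows] == ["0", "0", "0"]

    def test_totals_equal_annotation_rows(self, tmp_path, workspace):
        counts = pd.read_csv(
            workspace.bundle.class_counts_path, sep="\t", header=None
        )
        annotation = read_annotation_csv(workspace.bundle.annotation_csv_path)
        assert counts[1].sum() == len(annotation)


class TestAbundanceSummary:
    def test_top_n_per_type(self, tmp_path):
        records = [_rec(rpm=10.0 * (i + 1), seq="ACGU" * 5 + "ACG"[: i % 3])
                   for i in range(7)]
        path = write_abundance_summary(records, tmp_path / "ab.tsv", top_n=5)
        frame = pd.read_csv(path, sep="\t")
        assert len(frame) == 5
        assert list(frame.columns) == [
            "rRNA_type", "origin", "Category", "Sequence", "Length", "RPM",
            "Seq_count", "count",
        ]
        assert frame["RPM"].tolist() == sorted(frame["RPM"], reverse=True)

    def test_rpm_ties_break_by_sequence(self, tmp_path):
        records = [_rec(rpm=50.0, seq="C" * 20), _rec(rpm=50.0, seq="A" * 20)]
        path = write_abundance_summary(records, tmp_path / "ab.tsv", top_n=1)
        frame = pd.read_csv(path, sep="\t")
        assert frame["Sequence"].tolist() == ["A" * 20]


class TestHtmlReport:
    def test_empty_records_still_valid(self, tmp_path):
        path = write_html_report([], build_summary([]), [], tmp_path / "r.html")
        text = path.read_text()
        assert text.startswith("<!DOCTYPE html>")
        assert "</html>" in text

    def test_row_count_matches_records(self, tmp_path, workspace):
        annotation = read_annotation_csv(workspace.bundle.annotation_csv_path)
        html_text = workspace.bundle.html_path.read_text()
        # one header row + one row per record in the annotation table
        body = html_text.split("Annotated rsRNAs")[1]
        assert body.count("<tr>") == len(annotation) + 1

    def test_dot_bracket_column_present(self, workspace):
        assert "Dot_bracket" in workspace.bundle.html_path.read_text()

    def test_missing_figures_degrade_gracefully(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            path = write_html_report(
                [_rec()], build_summary([_rec()]),
                [tmp_path / "nope.png"], tmp_path / "r.html",
            )
        assert "missing figure" in path.read_text()


class TestFigures:
    def test_empty_input_warns_and_skips(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            paths = make_figures([], build_summary([]), tmp_path)
        assert paths == []
        assert "skipped" in caplog.text

    def test_fixture_figures_written_both_formats(self, tmp_path):
        records = [_rec(), _rec(category="rRF-i", origin="mitochondrial")]
        paths = make_figures(records, build_summary(records), tmp_path)
        names = sorted(p.name for p in paths)
        assert names == sorted(
            f"{stem}.{fmt}"
            for stem in ("origin_pie", "category_bar", "length_box", "rpm_box")
            for fmt in ("png", "svg")
        )
        assert all(p.stat().st_size > 0 for p in paths)

    def test_pie_fractions_equal_origin_histogram(self, workspace):
        summary = build_summary(
            _read_records_from_csv(workspace.bundle.annotation_csv_path)
        )
        truth_origins = {"nuclear": 0, "mitochondrial": 0, "chloroplastic": 0}
        genes = {g.gene_id: g for g in workspace.ref.genes}
        for locus in workspace.truth.loci:
            truth_origins[genes[locus["gene_id"]].origin] += 1
        assert summary.origin_counts == truth_origins


def _read_records_from_csv(path):
    frame = read_annotation_csv(path)
    records = []
    for _, row in frame.iterrows():
        gene_id, loc, rrna_type = row["rRNA_info"].split("|")
        origin = ("mitochondrial" if "chrMt" in loc
                  else "chloroplastic" if "chrPt" in loc else "nuclear")
        records.append(
            RsRNARecord(
                category=row["Category"], gene_id=gene_id, rrna_info=row["rRNA_info"],
                rrna_type=rrna_type, origin=origin, gene_start=int(row["Gene_Start"]),
                gene_end=int(row["Gene End"]), sequence=row["Sequence"],
                genomic_start=int(row["Genomic Start"]),
                genomic_end=int(row["Genomic End"]),
                difference=int(row["Difference"]), rpm=float(row["RPM"]),
                seq_count=int(row["Seq_count"]), count=int(row["count"]),
            )
        )
    return records
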