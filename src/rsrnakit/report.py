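"""Report generation: annotation CSV, abundance summary, class counts, HTML, figures.

The annotation CSV column order (and its two inconsistent header
spellings, ``Gene_Start`` but ``Gene End``) is fixed and treated as a
stable output contract. All writers are deterministic: rerunning on
identical records produces byte-identical files, including the figures
(matplotlib metadata that would embed a timestamp is suppressed).
"""

from __future__ import annotations

import base64
import html
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from rsrnakit.alignment import ExclusivityStats
from rsrnakit.classify import CATEGORIES, RsRNARecord
from rsrnakit.fold import fold_dot_bracket

logger = logging.getLogger(__name__)

#: annotation CSV header, in fixed order
ANNOTATION_COLUMNS = [
    "Category",
    "rRNA_info",
    "Gene_Start",
    "Gene End",
    "Sequence",
    "Length",
    "Genomic Start",
    "Genomic End",
    "Difference",
    "RPM",
    "Seq_count",
    "count",
]

ABUNDANCE_COLUMNS = [
    "rRNA_type",
    "origin",
    "Category",
    "Sequence",
    "Length",
    "RPM",
    "Seq_count",
    "count",
]

ORIGINS = ("nuclear", "mitochondrial", "chloroplastic")


@dataclass
class SampleSummary:
    """Per-sample roll-up used by the HTML report and the figures."""

    category_counts: dict[str, int] = field(default_factory=dict)
    origin_counts: dict[str, int] = field(default_factory=dict)
    length_counts: dict[int, int] = field(default_factory=dict)
    exclusivity: ExclusivityStats | None = None


@dataclass
class ReportBundle:
    """Paths of every file a reporting run produced."""

    annotation_csv_path: Path
    abundance_path: Path
    class_counts_path: Path
    html_path: Path
    figure_paths: list[Path] = field(default_factory=list)


def build_summary(
    records: Sequence[RsRNARecord], stats: ExclusivityStats | None = None
) -> SampleSummary:
    summary = SampleSummary(exclusivity=stats)
    summary.category_counts = {c: 0 for c in CATEGORIES}
    summary.origin_counts = {o: 0 for o in ORIGINS}
    for rec in records:
        summary.category_counts[rec.category] = (
            summary.category_counts.get(rec.category, 0) + 1
        )
        summary.origin_counts[rec.origin] = summary.origin_counts.get(rec.origin, 0) + 1
        summary.length_counts[rec.length] = summary.length_counts.get(rec.length, 0) + 1
    return summary


def records_to_frame(records: Sequence[RsRNARecord]) -> pd.DataFrame:
    """Annotation table as a DataFrame in the fixed column order."""
    rows = [
        {
            "Category": r.category,
            "rRNA_info": r.rrna_info,
            "Gene_Start": r.gene_start,
            "Gene End": r.gene_end,
            "Sequence": r.sequence,
            "Length": r.length,
            "Genomic Start": r.genomic_start,
            "Genomic End": r.genomic_end,
            "Difference": r.difference,
            "RPM": round(r.rpm, 2),
            "Seq_count": r.seq_count,
            "count": r.count,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation_csv(records: Sequence[RsRNARecord], path: str | Path) -> Path:
    """Write the 12-column annotation CSV (RPM at 2 decimals)."""
    path = Path(path)
    frame = records_to_frame(records)
    frame["RPM"] = [f"{r.rpm:.2f}" for r in records]
    frame.to_csv(path, index=False)
    return path


def read_annotation_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"RPM": float})


def write_class_counts(records: Sequence[RsRNARecord], path: str | Path) -> Path:
    """Two-column TSV with the per-category record counts (all three rows)."""
    path = Path(path)
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    with path.open("w") as fh:
        for category in CATEGORIES:
            fh.write(f"{category}\t{counts[category]}\n")
    return path


def write_abundance_summary(
    records: Sequence[RsRNARecord], path: str | Path, top_n: int = 5
) -> Path:
    """Eight-column abundance table: top-N records per rRNA type by RPM.

    Ties at rank N break deterministically by (RPM descending,
    sequence ascending).
    """
    path = Path(path)
    by_type: dict[str, list[RsRNARecord]] = {}
    for r in records:
        by_type.setdefault(r.rrna_type, []).append(r)
    rows = []
    for rrna_type in sorted(by_type):
        ranked = sorted(by_type[rrna_type], key=lambda r: (-r.rpm, r.sequence))
        for r in ranked[:top_n]:
            rows.append(
                {
                    "rRNA_type": r.rrna_type,
                    "origin": r.origin,
                    "Category": r.category,
                    "Sequence": r.sequence,
                    "Length": r.length,
                    "RPM": f"{r.rpm:.2f}",
                    "Seq_count": r.seq_count,
                    "count": r.count,
                }
            )
    pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def make_figures(
    records: Sequence[RsRNARecord],
    summary: SampleSummary,
    outdir: str | Path,
    formats: Sequence[str] = ("png", "svg"),
) -> list[Path]:
    """Write the four standard figures (pie, bar, two box plots).

    Returns an empty list (with a warning) on empty input. SVG output
    is made reproducible by pinning the element-id hash salt and
    dropping the date metadata.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not records:
        logger.warning("no records; figures skipped")
        return []

    with matplotlib.rc_context({"svg.hashsalt": "rsrnakit"}):
        paths: list[Path] = []
        frame = records_to_frame(records)

        fig, ax = plt.subplots(figsize=(5, 5))
        origins = [o for o in ORIGINS if summary.origin_counts.get(o, 0)]
        ax.pie(
            [summary.origin_counts[o] for o in origins],
            labels=origins,
            autopct="%1.1f%%",
            colors=sns.color_palette("muted", len(origins)),
        )
        ax.set_title("rsRNA records by organellar origin")
        paths += _save(fig, outdir / "origin_pie", formats)

        fig, ax = plt.subplots(figsize=(5, 4))
        sns.barplot(
            x=list(CATEGORIES),
            y=[summary.category_counts.get(c, 0) for c in CATEGORIES],
            hue=list(CATEGORIES),
            legend=False,
            palette="muted",
            ax=ax,
        )
        ax.set_xlabel("category")
        ax.set_ylabel("records")
        ax.set_title("rsRNA records per category")
        paths += _save(fig, outdir / "category_bar", formats)

        fig, ax = plt.subplots(figsize=(5, 4))
        sns.boxplot(data=frame, x="Category", y="Length", order=list(CATEGORIES), ax=ax)
        ax.set_title("Fragment length by category")
        paths += _save(fig, outdir / "length_box", formats)

        fig, ax = plt.subplots(figsize=(5, 4))
        sns.boxplot(data=frame, x="Category", y="RPM", order=list(CATEGORIES), ax=ax)
        ax.set_yscale("log")
        ax.set_title("Abundance (RPM) by category")
        paths += _save(fig, outdir / "rpm_box", formats)

    return paths


def _save(fig, stem: Path, formats: Sequence[str]) -> list[Path]:
    out = []
    for fmt in formats:
        path = stem.with_suffix(f".{fmt}")
        fig.savefig(path, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
        out.append(path)
    plt.close(fig)
    return out


_HTML_TEMPLATE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>rsRNA report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; color: #222; }}
table {{ border-collapse: collapse; font-size: 0.85em; }}
th, td {{ border: 1px solid #bbb; padding: 3px 7px; text-align: left; }}
th {{ background: #eef; }}
tr:nth-child(even) {{ background: #f7f7fb; }}
.summary td {{ border: none; padding: 1px 10px 1px 0; }}
code {{ font-family: monospace; }}
</style>
</head>
<body>
<h1>rsRNA annotation report</h1>
<h2>Summary</h2>
<table class="summary">
{summary_rows}
</table>
<h2>Figures</h2>
{figures}
<h2>Annotated rsRNAs</h2>
<table>
<tr>{header_cells}</tr>
{table_rows}
</table>
</body>
</html>
"""


def write_html_report(
    records: Sequence[RsRNARecord],
    summary: SampleSummary,
    figures: Sequence[Path],
    path: str | Path,
) -> Path:
    """Write a self-contained HTML report.

    Shows the confidence-filtered annotation table with an extra
    dot-bracket structure column, the per-category / per-origin
    summaries, and the PNG figures embedded as base64 data URIs.
    Missing figure files degrade to a logged placeholder.
    """
    path = Path(path)
    frame = records_to_frame(records)
    frame["RPM"] = [f"{r.rpm:.2f}" for r in records]
    frame["Dot_bracket"] = [fold_dot_bracket(r.sequence) for r in records]

    header_cells = "".join(f"<th>{html.escape(c)}</th>" for c in frame.columns)
    table_rows = "\n".join(
        "<tr>" + "".join(f"<td>{html.escape(str(v))}</td>" for v in row) + "</tr>"
        for row in frame.itertuples(index=False)
    )

    summary_items = [("rsRNA records", str(len(records)))]
    summary_items += [
        (f"{c} records", str(summary.category_counts.get(c, 0))) for c in CATEGORIES
    ]
    summary_items += [
        (f"{o} records", str(summary.origin_counts.get(o, 0))) for o in ORIGINS
    ]
    if summary.exclusivity is not None:
        ex = summary.exclusivity
        summary_items += [
            ("reads mapped", str(ex.n_total_reads)),
            ("rRNA-space exclusive reads", str(ex.n_rrna_exclusive)),
            ("ambiguous reads", str(ex.n_ambiguous)),
            ("non-rRNA reads", str(ex.n_non_rrna)),
        ]
    summary_rows = "\n".join(
        f"<tr><td>{html.escape(k)}</td><td>{html.escape(v)}</td></tr>"
        for k, v in summary_items
    )

    figure_tags = []
    for fig_path in figures:
        fig_path = Path(fig_path)
        if fig_path.suffix != ".png":
            continue
        if not fig_path.exists():
            logger.warning("figure %s missing; placeholder inserted", fig_path)
            figure_tags.append(f"<p>[missing figure: {html.escape(fig_path.name)}]</p>")
            continue
        data = base64.b64encode(fig_path.read_bytes()).decode("ascii")
        figure_tags.append(
            f'<img alt="{html.escape(fig_path.stem)}" '
            f'src="data:image/png;base64,{data}">'
        )

    path.write_text(
        _HTML_TEMPLATE.format(
            summary_rows=summary_rows,
            figures="\n".join(figure_tags) or "<p>(no figures)</p>",
            header_cells=header_cells,
            table_rows=table_rows,
        )
    )
    return path


def write_exclusivity_stats(stats: ExclusivityStats, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"total_reads\t{stats.n_total_reads}\n")
        fh.write(f"rrna_exclusive\t{stats.n_rrna_exclusive}\n")
        fh.write(f"ambiguous\t{stats.n_ambiguous}\n")
        fh.write(f"non_rrna\t{stats.n_non_rrna}\n")
        fh.write(f"exclusive_fraction\t{stats.exclusive_fraction:.4f}\n")
    return path
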