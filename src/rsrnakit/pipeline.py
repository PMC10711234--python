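"""Stage orchestration with content-digest freshness checks.

The stage graph is reference -> (per sample) filter -> classify ->
report. Every stage records the SHA-256 digests of its input files and
a hash of its parameters in a JSON manifest; on a re-run a stage whose
outputs all exist and whose recorded digests and parameters are
unchanged is skipped. Digests (not timestamps) make the check survive
file copies. Stages write into a scratch directory and move outputs
into place atomically, so a failed stage leaves nothing at a final
output path.

Layout under ``output_dir`` (``<genome>`` is the genome FASTA stem):

    intermediate/<genome>/            masked genome, transcripts, mask log
    intermediate/<genome>/<sample>/   filtered alignments, exclusivity stats
    result/<genome>/<sample>/         annotation CSV, abundance TSV,
                                      class counts, HTML, figures
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from rsrnakit import alignment, classify, reference, report
from rsrnakit.config import PipelineConfig

logger = logging.getLogger(__name__)


class SampleError(RuntimeError):
    """A per-sample stage failed; other samples continue."""


@dataclass
class StageResult:
    name: str
    skipped: bool
    outputs: list[Path] = field(default_factory=list)


@dataclass
class RunReport:
    bundles: dict[str, report.ReportBundle] = field(default_factory=dict)
    stages: list[StageResult] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()


class Manifest:
    """JSON-backed per-genome record of stage inputs/outputs/parameters."""

    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {}
        if path.exists():
            try:
                self.data = json.loads(path.read_text())
            except (json.JSONDecodeError, OSError) as exc:
                logger.warning("manifest %s unreadable (%s); all stages re-run", path, exc)
                self.data = {}

    def is_fresh(self, stage: str, inputs: Sequence[Path], params: Mapping,
                 outputs: Sequence[Path]) -> bool:
        entry = self.data.get(stage)
        if entry is None:
            return False
        if not all(Path(o).exists() for o in outputs):
            return False
        if entry.get("params") != _params_hash(params):
            return False
        recorded = entry.get("inputs", {})
        current = {str(p): _sha256(Path(p)) for p in inputs}
        return recorded == current

    def record(self, stage: str, inputs: Sequence[Path], params: Mapping,
               outputs: Sequence[Path]) -> None:
        self.data[stage] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "params": _params_hash(params),
            "outputs": [str(o) for o in outputs],
        }

    def save(self) -> None:
        self.path.parent.mkdir(parents=True, exist_ok=True)
        tmp = self.path.with_name(self.path.name + ".tmp")
        tmp.write_text(json.dumps(self.data, indent=1, sort_keys=True))
        tmp.replace(self.path)


def _run_stage(
    manifest: Manifest,
    name: str,
    inputs: Sequence[Path],
    params: Mapping,
    outputs: Sequence[Path],
    producer: Callable[[Path], None],
) -> StageResult:
    """Run ``producer`` in a scratch dir and atomically install outputs.

    ``producer`` must create, inside the scratch dir, a file of the
    same basename for every path in ``outputs`` (subdirectories allowed
    via relative layout).
    """
    if manifest.is_fresh(name, inputs, params, outputs):
        logger.info("stage %s: skipped (fresh)", name)
        return StageResult(name=name, skipped=True, outputs=list(outputs))
    logger.info("stage %s: running", name)
    with tempfile.TemporaryDirectory(prefix=f"{name.replace('/', '_')}.") as tmp:
        tmpdir = Path(tmp)
        producer(tmpdir)
        staged = []
        for out in outputs:
            src = tmpdir / Path(out).name
            if not src.exists():
                raise RuntimeError(f"stage {name} did not produce {Path(out).name}")
            staged.append((src, Path(out)))
        for src, dst in staged:
            dst.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(str(src), str(dst))
    manifest.record(name, inputs, params, outputs)
    manifest.save()
    return StageResult(name=name, skipped=False, outputs=list(outputs))


def discover_samples(config: PipelineConfig) -> dict[str, Path]:
    """Find ``<sample>.sam`` alignment files for the run."""
    samples: dict[str, Path] = {}
    if config.alignment_dir and Path(config.alignment_dir).is_dir():
        for path in sorted(Path(config.alignment_dir).glob("*.sam")):
            samples[path.stem] = path
    return samples


def _library_total(config: PipelineConfig, sample: str, sam_path: Path) -> int:
    """RPM denominator: reads in the trimmed FASTQ when available, else
    distinct read ids in the SAM."""
    if config.trimmed_dir:
        for suffix in (".fastq", ".fq"):
            fq = Path(config.trimmed_dir) / f"{sample}{suffix}"
            if fq.exists():
                with fq.open() as fh:
                    return sum(1 for _ in fh) // 4
    reads = alignment.read_alignments(sam_path)
    return len({r.read_id for r in reads})


def reference_paths(config: PipelineConfig) -> dict[str, Path]:
    genome_name = Path(config.genome_fasta).stem
    base = Path(config.output_dir) / "intermediate" / genome_name
    return {
        "masked": base / "artificial_genome.fa",
        "transcripts": base / "rrna_transcripts.fa",
        "mask_log": base / "mask_log.bed",
        "genes": base / "rrna_genes.tsv",
    }


def build_reference(config: PipelineConfig, manifest: Manifest | None = None) -> StageResult:
    """Reference stage: parse annotation, mask genome, extract transcripts."""
    paths = reference_paths(config)
    if manifest is None:
        manifest = Manifest(paths["masked"].parent / "manifest.json")
    inputs = [Path(config.genome_fasta), Path(config.species_ncbi_feature_table)]
    params = {"flank": config.flank, "header_map": config.header_map}

    def producer(tmpdir: Path) -> None:
        genome = reference.read_fasta(config.genome_fasta)
        hdr_report = reference.validate_genome_headers(genome)
        if not hdr_report.valid:
            logger.warning("non-conventional genome headers: %s", hdr_report.violations)
        genes = reference.parse_feature_table(
            config.species_ncbi_feature_table, config.header_map or None
        )
        masked = reference.mask_genome(genome, genes, flank=config.flank)
        transcripts = reference.extract_rrna_sequences(genome, genes)
        reference.write_fasta(masked.sequences, tmpdir / paths["masked"].name)
        reference.write_fasta(transcripts, tmpdir / paths["transcripts"].name)
        reference.write_mask_log(masked, tmpdir / paths["mask_log"].name)
        with (tmpdir / paths["genes"].name).open("w") as fh:
            fh.write("gene_id\tchromosome\tfasta_header\tstart\tend\tstrand\t"
                     "rrna_type\torigin\n")
            for g in genes:
                fh.write(f"{g.gene_id}\t{g.chromosome}\t{g.fasta_header}\t{g.start}\t"
                         f"{g.end}\t{g.strand}\t{g.rrna_type}\t{g.origin}\n")

    return _run_stage(manifest, "reference", inputs, params, list(paths.values()), producer)


def load_reference_genes(config: PipelineConfig) -> list[reference.RRNAGene]:
    genes_path = reference_paths(config)["genes"]
    genes = []
    with genes_path.open() as fh:
        next(fh)
        for line in fh:
            gene_id, chrom, header, start, end, strand, rrna_type, _origin = (
                line.rstrip("\n").split("\t")
            )
            genes.append(
                reference.RRNAGene(
                    gene_id=gene_id,
                    chromosome=chrom,
                    fasta_header=header,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    rrna_type=rrna_type,
                )
            )
    return genes


def run_sample(
    config: PipelineConfig,
    sample: str,
    sam_path: Path,
    genes: Sequence[reference.RRNAGene],
    manifest: Manifest,
) -> report.ReportBundle:
    genome_name = Path(config.genome_fasta).stem
    inter = Path(config.output_dir) / "intermediate" / genome_name / sample
    result = Path(config.output_dir) / "result" / genome_name / sample

    filtered_tsv = inter / "filtered_alignments.tsv"
    excl_tsv = inter / "exclusivity.tsv"
    thresholds = {
        "max_hits": config.max_hits,
        "flank": config.flank,
    }

    def filter_producer(tmpdir: Path) -> None:
        reads = alignment.read_alignments(sam_path)
        grouped = alignment.group_by_read(reads)
        space = alignment.RRNASpace.from_genes(genes, flank=config.flank)
        retained, stats = alignment.partition_rrna_exclusive(
            grouped, space, max_hits=config.max_hits
        )
        with (tmpdir / filtered_tsv.name).open("w") as fh:
            fh.write("read_id\tsequence\ttarget_id\ttarget_start\ttarget_end\t"
                     "strand\tdifference\thit_count\n")
            for r in retained:
                fh.write(f"{r.read_id}\t{r.sequence}\t{r.target_id}\t{r.target_start}"
                         f"\t{r.target_end}\t{r.strand}\t{r.difference}\t{r.hit_count}\n")
        report.write_exclusivity_stats(stats, tmpdir / excl_tsv.name)

    stage = _run_stage(
        manifest,
        f"filter/{sample}",
        [sam_path, reference_paths(config)["genes"]],
        thresholds,
        [filtered_tsv, excl_tsv],
        filter_producer,
    )

    records_tsv = inter / "rsrna_records.tsv"
    quant_params = {
        "min_rpm": config.min_rpm,
        "max_difference": config.max_difference,
        "length_range": config.length_range,
        "include_antisense": config.include_antisense,
    }
    library_total = _library_total(config, sample, sam_path)

    def classify_producer(tmpdir: Path) -> None:
        retained = _read_filtered(filtered_tsv)
        classified = classify.classify_reads(retained, genes)
        classified = classify.length_filter(classified, config.length_range)
        loci = classify.aggregate_loci(classified, genes)
        ctx = classify.LibraryContext(
            library_total=library_total,
            min_rpm=config.min_rpm,
            max_difference=config.max_difference,
            length_range=config.length_range,
        )
        records = classify.filter_confident(
            loci, ctx, include_antisense=config.include_antisense
        )
        frame = report.records_to_frame(records)
        frame.insert(0, "gene_id", [r.gene_id for r in records])
        frame.insert(1, "origin", [r.origin for r in records])
        frame.insert(2, "rRNA_type", [r.rrna_type for r in records])
        frame.insert(3, "sense", ["+" if r.sense else "-" for r in records])
        frame["RPM"] = [repr(r.rpm) for r in records]
        frame.to_csv(tmpdir / records_tsv.name, sep="\t", index=False)

    _run_stage(
        manifest,
        f"classify/{sample}",
        [filtered_tsv, reference_paths(config)["genes"]],
        {**quant_params, "library_total": library_total},
        [records_tsv],
        classify_producer,
    )

    annotation = result / "rsrna_annotation.csv"
    abundance = result / "rsrna_abundance.tsv"
    class_counts = result / "rsrna_class_counts.tsv"
    html = result / "rsrna_report.html"
    figdir = result / "figures"
    fig_names = [
        f"{stem}.{fmt}"
        for stem in ("origin_pie", "category_bar", "length_box", "rpm_box")
        for fmt in ("png", "svg")
    ]
    report_outputs = [annotation, abundance, class_counts, html] + [
        figdir / n for n in fig_names
    ]

    def report_producer(tmpdir: Path) -> None:
        records = _read_records(records_tsv, genes)
        stats = _read_exclusivity(excl_tsv)
        summary = report.build_summary(records, stats)
        report.write_annotation_csv(records, tmpdir / annotation.name)
        report.write_abundance_summary(
            records, tmpdir / abundance.name, top_n=config.top_n_abundance
        )
        report.write_class_counts(records, tmpdir / class_counts.name)
        figures = report.make_figures(records, summary, tmpdir)
        report.write_html_report(records, summary, figures, tmpdir / html.name)

    _run_stage(
        manifest,
        f"report/{sample}",
        [records_tsv, excl_tsv],
        {"top_n": config.top_n_abundance},
        report_outputs,
        report_producer,
    )

    return report.ReportBundle(
        annotation_csv_path=annotation,
        abundance_path=abundance,
        class_counts_path=class_counts,
        html_path=html,
        figure_paths=[figdir / n for n in fig_names],
    )


def _read_filtered(path: Path) -> list[alignment.AlignedRead]:
    reads = []
    with path.open() as fh:
        next(fh)
        for line in fh:
            rid, seq, tid, ts, te, strand, diff, hits = line.rstrip("\n").split("\t")
            reads.append(
                alignment.AlignedRead(
                    read_id=rid,
                    sequence=seq,
                    target_id=tid,
                    target_start=int(ts),
                    target_end=int(te),
                    strand=strand,
                    difference=int(diff),
                    hit_count=int(hits),
                )
            )
    return reads


def _read_records(path: Path, genes: Sequence[reference.RRNAGene]) -> list[classify.RsRNARecord]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype={"RPM": float})
    records = []
    for _, row in frame.iterrows():
        records.append(
            classify.RsRNARecord(
                category=row["Category"],
                gene_id=row["gene_id"],
                rrna_info=row["rRNA_info"],
                rrna_type=str(row["rRNA_type"]),
                origin=row["origin"],
                gene_start=int(row["Gene_Start"]),
                gene_end=int(row["Gene End"]),
                sequence=row["Sequence"],
                genomic_start=int(row["Genomic Start"]),
                genomic_end=int(row["Genomic End"]),
                difference=int(row["Difference"]),
                rpm=float(row["RPM"]),
                seq_count=int(row["Seq_count"]),
                count=int(row["count"]),
                sense=row["sense"] == "+",
            )
        )
    return records


def _read_exclusivity(path: Path) -> alignment.ExclusivityStats:
    values: dict[str, str] = {}
    with path.open() as fh:
        next(fh)
        for line in fh:
            key, value = line.rstrip("\n").split("\t")
            values[key] = value
    return alignment.ExclusivityStats(
        n_total_reads=int(values["total_reads"]),
        n_rrna_exclusive=int(values["rrna_exclusive"]),
        n_ambiguous=int(values["ambiguous"]),
        n_non_rrna=int(values["non_rrna"]),
    )


def run_pipeline(
    config: PipelineConfig,
    samples: Mapping[str, Path] | None = None,
) -> RunReport:
    """Execute the full stage graph for every sample.

    A failing sample is reported and skipped; remaining samples still
    run (callers map failures to a non-zero exit).
    """
    if samples is None:
        samples = discover_samples(config)
    run = RunReport()
    manifest = Manifest(
        Path(config.output_dir)
        / "intermediate"
        / Path(config.genome_fasta).stem
        / "manifest.json"
    )
    run.stages.append(build_reference(config, manifest))
    genes = load_reference_genes(config)
    for sample in sorted(samples):
        try:
            run.bundles[sample] = run_sample(
                config, sample, Path(samples[sample]), genes, manifest
            )
        except Exception as exc:  # noqa: BLE001 - sample isolation boundary
            logger.error("sample %s failed: %s", sample, exc)
            run.failures[sample] = str(exc)
    return run


def dry_run(config: PipelineConfig, samples: Mapping[str, Path] | None = None) -> str:
    """Report which stages would run or be skipped; writes nothing."""
    if samples is None:
        samples = discover_samples(config)
    manifest = Manifest(
        Path(config.output_dir)
        / "intermediate"
        / Path(config.genome_fasta).stem
        / "manifest.json"
    )
    lines = []
    ref_paths = reference_paths(config)
    ref_fresh = manifest.is_fresh(
        "reference",
        [Path(config.genome_fasta), Path(config.species_ncbi_feature_table)],
        {"flank": config.flank, "header_map": config.header_map},
        list(ref_paths.values()),
    )
    lines.append(f"reference: {'would skip (fresh)' if ref_fresh else 'would run'}")
    for sample in sorted(samples):
        for stage in ("filter", "classify", "report"):
            name = f"{stage}/{sample}"
            # downstream freshness is conservative: if the reference would
            # re-run, everything downstream re-runs too
            fresh = ref_fresh and name in manifest.data and all(
                Path(o).exists() for o in manifest.data[name].get("outputs", [])
            )
            lines.append(f"{name}: {'would skip (fresh)' if fresh else 'would run'}")
    return "\n".join(lines)
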