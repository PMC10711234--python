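"""Reference construction: rRNA gene extraction and genome masking.

Builds the two references the downstream stages align against:

* an *artificial genome* in which every annotated rRNA gene (optionally
  plus flanking bases) is replaced by ``N``, so that any read aligning
  to remaining genome space is demonstrably of non-rRNA origin;
* the rRNA transcript sequences themselves, extracted strand-aware so
  that position 1 of each record is the transcript 5' end.

rRNA genes are taken from an NCBI assembly feature table. All genomic
coordinates are 1-based inclusive throughout the package; only the
BED-style mask log is emitted 0-based half-open, as the format requires.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from Bio.Seq import Seq

logger = logging.getLogger(__name__)

MASK_CHAR = "N"

_HEADER_RE = re.compile(r"^chr(\d+|Mt|Pt)$")

#: chromosome-label aliases for the two organellar genomes (matched
#: case-insensitively after stripping any "chr" prefix)
_MT_ALIASES = {"mt", "mito", "mitochondrion", "mitochondria"}
_PT_ALIASES = {"pt", "pltd", "chloroplast", "plastid"}


class FeatureTableError(ValueError):
    """Malformed NCBI feature table (missing header, bad columns, bad row)."""


class ReferenceError(ValueError):
    """A gene refers to a sequence absent from the genome."""


@dataclass(frozen=True)
class RRNAGene:
    """One annotated rRNA gene.

    Coordinates are 1-based inclusive on the genomic sequence named by
    ``fasta_header``. ``origin`` is derived from the header: ``chrMt``
    is mitochondrial, ``chrPt`` chloroplastic, everything else nuclear.
    """

    gene_id: str
    chromosome: str
    fasta_header: str
    start: int
    end: int
    strand: str
    rrna_type: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FeatureTableError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FeatureTableError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def origin(self) -> str:
        if self.fasta_header == "chrMt":
            return "mitochondrial"
        if self.fasta_header == "chrPt":
            return "chloroplastic"
        return "nuclear"


@dataclass
class MaskedGenome:
    """Masked sequences plus a log of every masked interval (1-based)."""

    sequences: dict[str, str]
    mask_log: list[tuple[str, int, int, str]] = field(default_factory=list)


@dataclass
class HeaderValidationReport:
    """Outcome of genome header validation; empty violations == valid."""

    violations: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations


def map_chromosome_label(label: str) -> str | None:
    """Map an NCBI chromosome label to the pipeline's FASTA header convention.

    Nuclear chromosomes become ``chr<label>``; mitochondrial and plastid
    aliases become ``chrMt`` / ``chrPt``. Returns None for labels that
    cannot be mapped (caller decides whether to warn or fail).
    """
    bare = label.strip()
    if bare.lower().startswith("chr"):
        bare = bare[3:]
    low = bare.lower()
    if low in _MT_ALIASES:
        return "chrMt"
    if low in _PT_ALIASES:
        return "chrPt"
    if bare.isdigit():
        return f"chr{bare}"
    return None


def parse_feature_table(
    path: str | Path,
    header_map: Mapping[str, str] | None = None,
) -> list[RRNAGene]:
    """Extract rRNA genes from an NCBI assembly feature table.

    Only rows whose ``feature`` field equals ``rRNA`` are used ("gene"
    rows carrying an rRNA class would double-count the same interval).
    Rows on chromosomes that map to no FASTA header are skipped with a
    warning. The result is sorted by (fasta_header, start) so repeated
    parses are byte-reproducible downstream.

    Parameters
    ----------
    path:
        Tab-delimited feature table; the column header line starts with
        ``# feature``.
    header_map:
        Optional override mapping raw chromosome labels to FASTA
        headers; consulted before the built-in convention.
    """
    path = Path(path)
    columns: list[str] | None = None
    genes: list[RRNAGene] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("# feature"):
                    columns = line.lstrip("#").strip().split("\t")
                    if len(set(columns)) != len(columns):
                        raise FeatureTableError(
                            f"{path}: duplicate column names in header"
                        )
                continue
            if columns is None:
                raise FeatureTableError(
                    f"{path}: data before '# feature' header line (line {lineno})"
                )
            fields = line.split("\t")
            row = dict(zip(columns, fields))
            if row.get("feature") != "rRNA":
                continue
            try:
                gene = _row_to_gene(row, header_map)
            except KeyError as exc:
                raise FeatureTableError(
                    f"{path}: line {lineno} missing column {exc}"
                ) from exc
            except FeatureTableError as exc:
                raise FeatureTableError(f"{path}: line {lineno}: {exc}") from exc
            if gene is None:
                logger.warning(
                    "%s: line %d: chromosome %r has no FASTA header mapping; "
                    "row skipped",
                    path,
                    lineno,
                    row.get("chromosome"),
                )
                continue
            genes.append(gene)
    if columns is None:
        raise FeatureTableError(f"{path}: no '# feature' header line found")
    genes.sort(key=lambda g: (g.fasta_header, g.start))
    return genes


def _row_to_gene(
    row: Mapping[str, str], header_map: Mapping[str, str] | None
) -> RRNAGene | None:
    chromosome = row["chromosome"]
    fasta_header = None
    if header_map and chromosome in header_map:
        fasta_header = header_map[chromosome]
    else:
        fasta_header = map_chromosome_label(chromosome)
    if fasta_header is None:
        return None
    start = int(row["start"])
    end = int(row["end"])
    strand = row["strand"]
    name = row.get("name", "") or row.get("symbol", "") or "rRNA"
    locus_tag = row.get("locus_tag", "")
    gene_id = locus_tag or f"{name.split()[0]}_{fasta_header}_{start}_{end}"
    # "18S ribosomal RNA" -> "18S"; single-token names pass through
    rrna_type = name.split()[0] if name else "rRNA"
    return RRNAGene(
        gene_id=gene_id,
        chromosome=chromosome,
        fasta_header=fasta_header,
        start=start,
        end=end,
        strand=strand,
        rrna_type=rrna_type,
    )


def mask_genome(
    genome: Mapping[str, str],
    genes: Sequence[RRNAGene],
    flank: int = 0,
) -> MaskedGenome:
    """Replace every rRNA gene interval (± flank) with ``N``.

    Flanks are clipped at sequence ends; overlapping masks merge
    idempotently (masking an already-masked base is a no-op). Sequence
    lengths are conserved exactly.
    """
    if flank < 0:
        raise ValueError(f"flank must be >= 0, got {flank}")
    buffers = {h: bytearray(s.encode()) for h, s in genome.items()}
    log: list[tuple[str, int, int, str]] = []
    for gene in genes:
        if gene.fasta_header not in buffers:
            raise ReferenceError(
                f"gene {gene.gene_id}: sequence {gene.fasta_header!r} not in genome"
            )
        buf = buffers[gene.fasta_header]
        lo = max(1, gene.start - flank)
        hi = min(len(buf), gene.end + flank)
        buf[lo - 1 : hi] = MASK_CHAR.encode() * (hi - lo + 1)
        log.append((gene.fasta_header, lo, hi, gene.gene_id))
    return MaskedGenome(
        sequences={h: b.decode() for h, b in buffers.items()},
        mask_log=log,
    )


def extract_rrna_sequences(
    genome: Mapping[str, str], genes: Sequence[RRNAGene]
) -> dict[str, str]:
    """Extract each rRNA transcript from the (unmasked) genome.

    Minus-strand genes are reverse-complemented, so position 1 of every
    returned sequence is the transcript 5' end.
    """
    out: dict[str, str] = {}
    for gene in genes:
        if gene.fasta_header not in genome:
            raise ReferenceError(
                f"gene {gene.gene_id}: sequence {gene.fasta_header!r} not in genome"
            )
        seq = genome[gene.fasta_header][gene.start - 1 : gene.end]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out[gene.gene_id] = seq
    return out


def validate_genome_headers(genome: Iterable[str]) -> HeaderValidationReport:
    """Check FASTA headers against the ``chr<Num>`` / ``chrMt`` / ``chrPt`` convention."""
    report = HeaderValidationReport()
    for header in genome:
        if not _HEADER_RE.match(header):
            report.violations.append(header)
    return report


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered header -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        _write_fasta_handle(sequences, fh, width)


def _write_fasta_handle(sequences: Mapping[str, str], fh: TextIO, width: int) -> None:
    for header, seq in sequences.items():
        fh.write(f">{header}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_mask_log(masked: MaskedGenome, path: str | Path) -> None:
    """Write the mask log as BED (0-based half-open intervals)."""
    path = Path(path)
    with path.open("w") as fh:
        for header, start, end, gene_id in masked.mask_log:
            fh.write(f"{header}\t{start - 1}\t{end}\t{gene_id}\n")
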