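"""Positional classification, locus aggregation and RPM quantification.

A retained read is classified by where it sits on its parental rRNA
transcript: a fragment starting at transcript position 1 is a 5'-rRF
(``rRF-5``), a fragment ending at the final transcript position is a
3'-rRF (``rRF-3``), and anything strictly internal is an i-rRF
(``rRF-i``). A read spanning the full transcript satisfies both end
rules; it is assigned ``rRF-5`` (configurable), consistent with the
observed 5' skew of rsRNA populations.

Reads sharing (gene, start, end, sense) form a locus. The locus is
reported with its predominant sequence (``Seq_count`` of that sequence
vs the total ``count`` of reads at the locus), normalized to reads per
million (RPM), and passed through the confidence filters: edit
distance strictly below ``max_difference`` and abundance at least
``min_rpm``. Low-abundance entries co-located at identical genomic
coordinates are folded into the surviving locus so the overall read
count is conserved.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from rsrnakit.alignment import (
    AlignedRead,
    CoordinateError,
    gene_relative_coords,
    genomic_coords,
)
from rsrnakit.reference import RRNAGene

logger = logging.getLogger(__name__)

CATEGORIES = ("rRF-5", "rRF-3", "rRF-i")

DEFAULT_LENGTH_RANGE = (16, 40)
DEFAULT_MIN_RPM = 10.0
DEFAULT_MAX_DIFFERENCE = 4


@dataclass(frozen=True)
class LibraryContext:
    """Quantification context for one small-RNA library.

    ``library_total`` is the RPM denominator (total reads in the
    library by default). ``max_difference`` is an exclusive bound;
    ``min_rpm`` and the length bounds are inclusive.
    """

    library_total: int
    min_rpm: float = DEFAULT_MIN_RPM
    max_difference: int = DEFAULT_MAX_DIFFERENCE
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE

    def __post_init__(self) -> None:
        if self.library_total <= 0:
            raise ValueError(f"library_total must be > 0, got {self.library_total}")


@dataclass(frozen=True)
class ClassifiedRead:
    """One retained read in transcript coordinates, with its category."""

    read_id: str
    gene_id: str
    gene_start: int
    gene_end: int
    sense: bool
    sequence: str
    difference: int
    category: str


@dataclass(frozen=True)
class RsRNARecord:
    """One annotated rsRNA locus (one output row)."""

    category: str
    gene_id: str
    rrna_info: str
    rrna_type: str
    origin: str
    gene_start: int
    gene_end: int
    sequence: str
    genomic_start: int
    genomic_end: int
    difference: int
    rpm: float
    seq_count: int
    count: int
    sense: bool = True

    @property
    def length(self) -> int:
        return self.gene_end - self.gene_start + 1


@dataclass
class Locus:
    """Aggregated reads sharing (gene, gene_start, gene_end, sense)."""

    gene: RRNAGene
    gene_start: int
    gene_end: int
    sense: bool
    category: str
    sequence: str
    seq_count: int
    count: int
    difference: int
    seq_counts: dict[str, int] = field(default_factory=dict)


def classify_rrf(
    gene_start: int,
    gene_end: int,
    gene_length: int,
    full_span_category: str = "rRF-5",
) -> str:
    """Assign the positional category of a transcript interval.

    Start at position 1 -> rRF-5; end at the final position -> rRF-3;
    strictly internal -> rRF-i. A full-span interval takes
    ``full_span_category``.
    """
    if not (1 <= gene_start <= gene_end <= gene_length):
        raise ValueError(
            f"interval {gene_start}..{gene_end} outside transcript "
            f"coordinates [1, {gene_length}]"
        )
    if gene_start == 1 and gene_end == gene_length:
        return full_span_category
    if gene_start == 1:
        return "rRF-5"
    if gene_end == gene_length:
        return "rRF-3"
    return "rRF-i"


def length_filter(
    records: Iterable[ClassifiedRead],
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> list[ClassifiedRead]:
    """Retain reads whose length lies inside the inclusive rsRNA range."""
    lo, hi = length_range
    return [r for r in records if lo <= len(r.sequence) <= hi]


def classify_reads(
    reads: Sequence[AlignedRead],
    genes: Sequence[RRNAGene],
    full_span_category: str = "rRF-5",
) -> list[ClassifiedRead]:
    """Resolve retained alignments to transcript coordinates and classify.

    Alignments may target the extracted transcript directly or the
    genomic interval of the gene. Genomic alignments hanging over a
    transcript boundary have no defined category and are dropped with
    a warning.
    """
    by_id = {g.gene_id: g for g in genes}
    by_header: dict[str, list[RRNAGene]] = defaultdict(list)
    for g in genes:
        by_header[g.fasta_header].append(g)

    out: list[ClassifiedRead] = []
    for read in reads:
        gene = by_id.get(read.target_id)
        if gene is None:
            gene = next(
                (
                    g
                    for g in by_header.get(read.target_id, ())
                    if g.start <= read.target_start and read.target_end <= g.end
                ),
                None,
            )
        if gene is None:
            logger.warning(
                "read %s: alignment %s:%d..%d overlaps no rRNA transcript "
                "completely; dropped",
                read.read_id,
                read.target_id,
                read.target_start,
                read.target_end,
            )
            continue
        try:
            gstart, gend, sense = gene_relative_coords(read, gene)
        except CoordinateError as exc:
            logger.warning("%s; dropped", exc)
            continue
        out.append(
            ClassifiedRead(
                read_id=read.read_id,
                gene_id=gene.gene_id,
                gene_start=gstart,
                gene_end=gend,
                sense=sense,
                sequence=read.sequence,
                difference=read.difference,
                category=classify_rrf(gstart, gend, gene.length, full_span_category),
            )
        )
    return out


def aggregate_loci(
    reads: Sequence[ClassifiedRead], genes: Sequence[RRNAGene]
) -> list[Locus]:
    """Group classified reads into loci keyed by (gene, start, end, sense).

    The locus representative is the most frequent unique sequence; ties
    break toward the lower edit distance, then lexicographically. The
    locus ``difference`` is the smallest difference among reads
    carrying the representative sequence.
    """
    by_id = {g.gene_id: g for g in genes}
    groups: dict[tuple[str, int, int, bool], list[ClassifiedRead]] = defaultdict(list)
    for r in reads:
        groups[(r.gene_id, r.gene_start, r.gene_end, r.sense)].append(r)

    loci: list[Locus] = []
    for (gene_id, gstart, gend, sense), members in groups.items():
        gene = by_id[gene_id]
        seq_counts = Counter(m.sequence for m in members)
        min_diff = {
            seq: min(m.difference for m in members if m.sequence == seq)
            for seq in seq_counts
        }
        representative = min(
            seq_counts,
            key=lambda s: (-seq_counts[s], min_diff[s], s),
        )
        loci.append(
            Locus(
                gene=gene,
                gene_start=gstart,
                gene_end=gend,
                sense=sense,
                category=members[0].category,
                sequence=representative,
                seq_count=seq_counts[representative],
                count=len(members),
                difference=min_diff[representative],
                seq_counts=dict(seq_counts),
            )
        )
    loci.sort(key=lambda l: (l.gene.gene_id, l.gene_start, l.gene_end, not l.sense))
    return loci


def compute_rpm(count: int, library_total: int) -> float:
    """Reads-per-million normalization: count / library_total * 1e6."""
    if library_total <= 0:
        raise ValueError(f"library_total must be > 0, got {library_total}")
    return count / library_total * 1_000_000


def filter_confident(
    loci: Sequence[Locus],
    ctx: LibraryContext,
    include_antisense: bool = False,
) -> list[RsRNARecord]:
    """Apply the confidence filters and emit final rsRNA records.

    Keeps loci with ``difference < max_difference`` and
    ``RPM >= min_rpm``. Loci sharing identical genomic coordinates and
    strand are folded into the most abundant one (ties broken by RPM
    descending then sequence ascending): the minor entries disappear as
    records but their reads stay in the surviving locus ``count``.
    Antisense loci are excluded from the output by default.
    """
    candidates = [l for l in loci if l.difference < ctx.max_difference]
    if not include_antisense:
        candidates = [l for l in candidates if l.sense]

    colocated: dict[tuple[int, int, str], list[Locus]] = defaultdict(list)
    for locus in candidates:
        start, end = genomic_coords(locus.gene, locus.gene_start, locus.gene_end)
        strand = locus.gene.strand if locus.sense else ("-" if locus.gene.strand == "+" else "+")
        colocated[(start, end, strand)].append(locus)

    records: list[RsRNARecord] = []
    for (gstart, gend, _strand), group in colocated.items():
        group.sort(key=lambda l: (-compute_rpm(l.count, ctx.library_total), l.sequence))
        top = group[0]
        merged_count = sum(l.count for l in group)
        rpm = compute_rpm(merged_count, ctx.library_total)
        if rpm < ctx.min_rpm:
            continue
        gene = top.gene
        records.append(
            RsRNARecord(
                category=top.category,
                gene_id=gene.gene_id,
                rrna_info=(
                    f"{gene.gene_id}|{gene.fasta_header}:"
                    f"{gene.start}-{gene.end}({gene.strand})|{gene.rrna_type}"
                ),
                rrna_type=gene.rrna_type,
                origin=gene.origin,
                gene_start=top.gene_start,
                gene_end=top.gene_end,
                sequence=top.sequence,
                genomic_start=gstart,
                genomic_end=gend,
                difference=top.difference,
                rpm=rpm,
                seq_count=top.seq_count,
                count=merged_count,
                sense=top.sense,
            )
        )
    records.sort(key=lambda r: (r.origin, r.gene_id, r.gene_start, r.gene_end))
    return records


def annotate_modification_overlap(
    records: Sequence[RsRNARecord],
    sites: Sequence[tuple[str, int, str]],
    genes: Mapping[str, RRNAGene] | None = None,
) -> tuple[list[list[tuple[str, int, str]]], dict[str, int]]:
    """Overlap rsRNA records with rRNA modification sites.

    ``sites`` rows are (gene_id, 1-based transcript position, type),
    type typically ``methylation`` or ``pseudouridylation``. A site
    overlaps a record iff it lies inside the record's transcript
    interval on the same gene. Returns the per-record site lists
    (parallel to ``records``) and the total overlapping-site count per
    modification type. Sites beyond the gene length are skipped with a
    warning.
    """
    valid: list[tuple[str, int, str]] = []
    for gene_id, pos, mod_type in sites:
        if genes is not None and gene_id in genes and not (1 <= pos <= genes[gene_id].length):
            logger.warning(
                "modification site %s:%d (%s) outside gene length %d; skipped",
                gene_id,
                pos,
                mod_type,
                genes[gene_id].length,
            )
            continue
        valid.append((gene_id, pos, mod_type))

    per_record: list[list[tuple[str, int, str]]] = []
    totals: dict[str, int] = defaultdict(int)
    for rec in records:
        hits = [
            s
            for s in valid
            if s[0] == rec.gene_id and rec.gene_start <= s[1] <= rec.gene_end
        ]
        per_record.append(hits)
        for _, _, mod_type in hits:
            totals[mod_type] += 1
    return per_record, dict(totals)


def with_rpm(locus: Locus, ctx: LibraryContext) -> float:
    return compute_rpm(locus.count, ctx.library_total)
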