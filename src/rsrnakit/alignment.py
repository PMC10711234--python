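"""SAM ingestion, per-alignment difference counting, and rRNA-space filtering.

Reads are aligned (upstream, by any SAM-emitting aligner) against the
joint reference of the artificial genome plus the extracted rRNA
transcripts. A read is usable for rsRNA annotation only if *all* of its
reported alignments fall inside rRNA space: a read with at least one
alignment in remaining (masked) genome space is ambiguous and dropped,
and a read aligning only outside rRNA space is of non-rRNA origin.

The per-alignment ``difference`` is the aligner's edit distance:
mismatches plus inserted plus deleted bases. The NM tag is trusted when
present; otherwise it is reconstructed from the MD string and CIGAR.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio.Seq import Seq

from rsrnakit.reference import RRNAGene

logger = logging.getLogger(__name__)

DEFAULT_MAX_HITS = 50

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


class SamFormatError(ValueError):
    """Malformed SAM input."""


class DifferenceUndeterminable(ValueError):
    """Alignment carries neither NM nor MD and CIGAR M ops hide mismatches."""


class CoordinateError(ValueError):
    """A read does not lie within the gene interval it was matched to."""


@dataclass(frozen=True)
class AlignedRead:
    """One alignment of one read.

    ``sequence`` is the read as sequenced (reverse-complemented back
    from the SAM record when the alignment is on the minus strand).
    ``target_id`` is either an rRNA transcript id or an artificial
    genome FASTA header; coordinates are 1-based inclusive on that
    target. ``hit_count`` is the number of alignments reported for the
    read across the whole file.
    """

    read_id: str
    sequence: str
    target_id: str
    target_start: int
    target_end: int
    strand: str
    difference: int
    hit_count: int = 1


@dataclass
class ExclusivityStats:
    """Partition of read ids by rRNA-space exclusivity."""

    n_total_reads: int = 0
    n_rrna_exclusive: int = 0
    n_ambiguous: int = 0
    n_non_rrna: int = 0

    def __post_init__(self) -> None:
        parts = self.n_rrna_exclusive + self.n_ambiguous + self.n_non_rrna
        if self.n_total_reads != parts:
            raise ValueError(
                f"partition does not sum: {parts} != total {self.n_total_reads}"
            )

    @property
    def exclusive_fraction(self) -> float:
        return self.n_rrna_exclusive / self.n_total_reads if self.n_total_reads else 0.0


@dataclass(frozen=True)
class RRNASpace:
    """The rRNA portion of the joint reference.

    An alignment is inside rRNA space iff its target is an rRNA
    transcript id, or it lies entirely within an annotated (optionally
    flank-extended) rRNA interval on a genomic sequence.
    """

    gene_ids: frozenset[str]
    genomic_intervals: Mapping[str, tuple[tuple[int, int], ...]]

    @classmethod
    def from_genes(cls, genes: Sequence[RRNAGene], flank: int = 0) -> "RRNASpace":
        by_header: dict[str, list[tuple[int, int]]] = {}
        for g in genes:
            by_header.setdefault(g.fasta_header, []).append(
                (g.start - flank, g.end + flank)
            )
        return cls(
            gene_ids=frozenset(g.gene_id for g in genes),
            genomic_intervals={h: tuple(sorted(v)) for h, v in by_header.items()},
        )

    def contains(self, read: AlignedRead) -> bool:
        if read.target_id in self.gene_ids:
            return True
        for lo, hi in self.genomic_intervals.get(read.target_id, ()):
            if lo <= read.target_start and read.target_end <= hi:
                return True
        return False


def compute_difference(
    cigar: str, nm: int | None = None, md: str | None = None
) -> int:
    """Edit distance of an alignment: mismatches + inserted + deleted bases.

    NM is authoritative when present. Otherwise mismatches are counted
    from the MD string and indel bases from the CIGAR. Soft- and
    hard-clipped bases are never differences.
    """
    if nm is not None:
        return int(nm)
    ops = _parse_cigar(cigar)
    inserted = sum(n for n, op in ops if op == "I")
    deleted = sum(n for n, op in ops if op == "D")
    if md is not None:
        return _md_mismatches(md) + inserted + deleted
    if any(op == "M" for _, op in ops):
        raise DifferenceUndeterminable(
            f"CIGAR {cigar!r} has M ops but neither NM nor MD is available"
        )
    mismatches = sum(n for n, op in ops if op == "X")
    return mismatches + inserted + deleted


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = re.findall(r"(\d+)([MIDNSHP=X])", cigar)
    if not ops or "".join(n + op for n, op in ops) != cigar:
        raise SamFormatError(f"invalid CIGAR string: {cigar!r}")
    return [(int(n), op) for n, op in ops]


def _md_mismatches(md: str) -> int:
    """Count mismatched reference bases in an MD string (deletions excluded)."""
    n = 0
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        pos = m.end()
        if m.group(3):
            n += 1
    if pos != len(md):
        raise SamFormatError(f"invalid MD string: {md!r}")
    return n


def read_alignments(sam_path: str | Path) -> list[AlignedRead]:
    """Parse mapped records of a SAM/BAM file into AlignedRead objects.

    Unmapped records and records without a CIGAR are skipped (the
    latter with a warning). ``hit_count`` is taken from the NH tag when
    present, otherwise from the number of records sharing the read id.
    """
    raw: list[tuple[AlignedRead, int | None]] = []
    per_read: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.cigarstring is None:
                logger.warning("read %s: mapped record without CIGAR, skipped", rec.query_name)
                continue
            seq = rec.query_sequence or ""
            if rec.is_reverse:
                seq = str(Seq(seq).reverse_complement())
            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            md = rec.get_tag("MD") if rec.has_tag("MD") else None
            diff = compute_difference(rec.cigarstring, nm, md)
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            read = AlignedRead(
                read_id=rec.query_name,
                sequence=seq,
                target_id=rec.reference_name,
                target_start=rec.reference_start + 1,
                target_end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                difference=diff,
                hit_count=1,
            )
            raw.append((read, nh))
            per_read[rec.query_name] = per_read.get(rec.query_name, 0) + 1
    out: list[AlignedRead] = []
    for read, nh in raw:
        hits = int(nh) if nh is not None else per_read[read.read_id]
        out.append(
            AlignedRead(**{**read.__dict__, "hit_count": hits})
            if hits != read.hit_count
            else read
        )
    return out


def group_by_read(reads: Iterable[AlignedRead]) -> dict[str, list[AlignedRead]]:
    grouped: dict[str, list[AlignedRead]] = {}
    for r in reads:
        grouped.setdefault(r.read_id, []).append(r)
    return grouped


def partition_rrna_exclusive(
    reads_by_id: Mapping[str, Sequence[AlignedRead]],
    rrna_space: RRNASpace,
    max_hits: int = DEFAULT_MAX_HITS,
) -> tuple[list[AlignedRead], ExclusivityStats]:
    """Retain reads whose every alignment falls inside rRNA space.

    Reads mixing rRNA and non-rRNA alignments are ambiguous and
    dropped; reads with only non-rRNA alignments are counted as
    non-rRNA. Reads exceeding ``max_hits`` alignments are flagged with
    a warning (mirroring the aligner's multi-mapping cap) but not
    dropped here.
    """
    retained: list[AlignedRead] = []
    n_excl = n_ambig = n_non = 0
    for read_id in reads_by_id:
        alns = reads_by_id[read_id]
        in_space = [rrna_space.contains(a) for a in alns]
        if alns and alns[0].hit_count > max_hits:
            logger.warning(
                "read %s: %d alignments exceeds the multimap cap of %d",
                read_id,
                alns[0].hit_count,
                max_hits,
            )
        if all(in_space):
            n_excl += 1
            retained.extend(alns)
        elif any(in_space):
            n_ambig += 1
        else:
            n_non += 1
    stats = ExclusivityStats(
        n_total_reads=len(reads_by_id),
        n_rrna_exclusive=n_excl,
        n_ambiguous=n_ambig,
        n_non_rrna=n_non,
    )
    return retained, stats


def gene_relative_coords(
    read: AlignedRead, gene: RRNAGene
) -> tuple[int, int, bool]:
    """Transform an alignment to 1-based transcript coordinates.

    Position 1 is the transcript 5' end. For alignments against the
    extracted transcript the coordinates pass through unchanged; for
    genomic alignments on a minus-strand gene the interval is reflected
    about the gene end. ``sense`` is True when the read strand matches
    the transcript orientation.
    """
    if read.target_id == gene.gene_id:
        if not (1 <= read.target_start <= read.target_end <= gene.length):
            raise CoordinateError(
                f"read {read.read_id}: {read.target_start}..{read.target_end} "
                f"outside transcript {gene.gene_id} (length {gene.length})"
            )
        return read.target_start, read.target_end, read.strand == "+"
    if read.target_id != gene.fasta_header or not (
        gene.start <= read.target_start and read.target_end <= gene.end
    ):
        raise CoordinateError(
            f"read {read.read_id} ({read.target_id}:{read.target_start}.."
            f"{read.target_end}) outside gene {gene.gene_id} "
            f"({gene.fasta_header}:{gene.start}..{gene.end})"
        )
    if gene.strand == "+":
        gstart = read.target_start - gene.start + 1
        gend = read.target_end - gene.start + 1
    else:
        gstart = gene.end - read.target_end + 1
        gend = gene.end - read.target_start + 1
    return gstart, gend, read.strand == gene.strand


def genomic_coords(gene: RRNAGene, gene_start: int, gene_end: int) -> tuple[int, int]:
    """Inverse of :func:`gene_relative_coords` for a transcript interval."""
    if not (1 <= gene_start <= gene_end <= gene.length):
        raise CoordinateError(
            f"{gene_start}..{gene_end} outside transcript of length {gene.length}"
        )
    if gene.strand == "+":
        return gene.start + gene_start - 1, gene.start + gene_end - 1
    return gene.end - gene_end + 1, gene.end - gene_start + 1
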