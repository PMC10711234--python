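"""Deterministic synthetic references, reads and alignments for pipeline testing.

Emulates the full input contract of the pipeline without any download
or external aligner: a toy genome with nuclear, mitochondrial and
plastid rRNA genes on both strands, an NCBI-dialect feature table, a
small-RNA read set drawn from rRF-5 / rRF-3 / rRF-i positions with
controlled mismatch counts, optional decoy and ambiguous reads, and a
truth-placement SAM (alignments are written from the simulation truth,
not computed, so tests exercise the post-alignment logic only).

Everything is driven by one integer seed through ``random.Random``;
identical seeds give byte-identical output files on any platform.
"""

from __future__ import annotations

import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

from rsrnakit.reference import RRNAGene

FEATURE_TABLE_COLUMNS = [
    "feature",
    "class",
    "assembly",
    "assembly_unit",
    "seq_type",
    "chromosome",
    "genomic_accession",
    "start",
    "end",
    "strand",
    "product_accession",
    "non-redundant_refseq",
    "related_accession",
    "name",
    "symbol",
    "GeneID",
    "locus_tag",
    "feature_interval_length",
    "product_length",
    "attributes",
]

_NUCLEAR_TYPES = ["18S", "25S", "5.8S", "5S"]
_MT_TYPES = ["26S", "18S"]
_PT_TYPES = ["16S", "23S"]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe the standard desk-scale test condition: six rRNA
    genes (four nuclear across two chromosomes, one mitochondrial, one
    plastid; strands alternate so both orientations occur), 5,000
    reads of 16-40 nt in a 5' -skewed category mix, error-free, with
    no decoy or ambiguous reads. The RPM denominator defaults to the
    total simulated read count.
    """

    seed: int = 42
    n_nuclear: int = 4
    n_mt: int = 1
    n_pt: int = 1
    n_nuclear_chromosomes: int = 2
    gene_length_range: tuple[int, int] = (150, 400)
    intergenic_range: tuple[int, int] = (80, 200)
    n_reads: int = 5000
    read_length_range: tuple[int, int] = (16, 40)
    category_fractions: tuple[float, float, float] = (0.5, 0.3, 0.2)
    antisense_fraction: float = 0.0
    loci_per_gene_category: int = 3
    mismatch_rate: float = 0.0
    max_mismatches: int = 3
    frac_decoy: float = 0.0
    frac_ambiguous: float = 0.0
    minor_variant_every: int = 0
    minor_variant_prob: float = 0.25
    out_of_range_fraction: float = 0.0
    library_total: int | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.category_fractions) - 1.0) > 1e-9:
            raise ValueError("category_fractions must sum to 1")
        if min(self.category_fractions) < 0:
            raise ValueError("category_fractions must be non-negative")
        if self.frac_decoy + self.frac_ambiguous > 1:
            raise ValueError("decoy + ambiguous fractions exceed 1")


@dataclass(frozen=True)
class SimRead:
    """One simulated read with its generation truth."""

    read_id: str
    sequence: str  # as sequenced
    kind: str  # rrna | decoy | ambiguous
    gene_id: str | None
    category: str | None
    gene_start: int | None
    gene_end: int | None
    sense: bool
    n_mismatches: int
    aligned_seq: str  # reference-strand sequence at the placement
    decoy_header: str | None = None
    decoy_start: int | None = None


@dataclass
class FixtureTruth:
    """Truth tables accompanying one simulated data set."""

    genes: list[RRNAGene]
    transcripts: dict[str, str]
    reads: list[SimRead]
    loci: list[dict] = field(default_factory=list)

    @property
    def library_total(self) -> int:
        return len(self.reads)


@dataclass
class FixtureReference:
    genome: dict[str, str]
    genes: list[RRNAGene]
    transcripts: dict[str, str]


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def generate_reference(spec: FixtureSpec) -> FixtureReference:
    """Build the toy genome and its rRNA annotation.

    Genes are placed non-overlapping with random intergenic spacers;
    strands alternate deterministically so that any fixture with at
    least two genes contains both orientations.
    """
    rng = random.Random(spec.seed)
    plan: list[tuple[str, list[str]]] = []
    nuclear_assign: dict[str, list[str]] = defaultdict(list)
    for i in range(spec.n_nuclear):
        chrom = f"chr{i % spec.n_nuclear_chromosomes + 1}"
        nuclear_assign[chrom].append(_NUCLEAR_TYPES[i % len(_NUCLEAR_TYPES)])
    for c in range(spec.n_nuclear_chromosomes):
        plan.append((f"chr{c + 1}", nuclear_assign.get(f"chr{c + 1}", [])))
    plan.append(("chrMt", [_MT_TYPES[i % len(_MT_TYPES)] for i in range(spec.n_mt)]))
    plan.append(("chrPt", [_PT_TYPES[i % len(_PT_TYPES)] for i in range(spec.n_pt)]))

    genome: dict[str, str] = {}
    genes: list[RRNAGene] = []
    gene_index = 0
    for header, types in plan:
        parts: list[str] = []
        pos = 0
        for rrna_type in types:
            gap = rng.randint(*spec.intergenic_range)
            glen = rng.randint(*spec.gene_length_range)
            parts.append(_random_seq(rng, gap))
            start = pos + gap + 1
            end = start + glen - 1
            parts.append(_random_seq(rng, glen))
            pos = end
            gene_index += 1
            strand = "+" if gene_index % 2 == 1 else "-"
            genes.append(
                RRNAGene(
                    gene_id=f"SYNR_{gene_index:04d}",
                    chromosome=_header_to_label(header),
                    fasta_header=header,
                    start=start,
                    end=end,
                    strand=strand,
                    rrna_type=rrna_type,
                )
            )
        tail = rng.randint(*spec.intergenic_range)
        parts.append(_random_seq(rng, tail))
        genome[header] = "".join(parts)

    transcripts = {}
    for g in genes:
        seq = genome[g.fasta_header][g.start - 1 : g.end]
        if g.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        transcripts[g.gene_id] = seq
    return FixtureReference(genome=genome, genes=genes, transcripts=transcripts)


def _header_to_label(header: str) -> str:
    if header == "chrMt":
        return "MT"
    if header == "chrPt":
        return "Pltd"
    return header[3:]


def write_feature_table(ref: FixtureReference, path: str | Path) -> Path:
    """Write the annotation in the NCBI assembly feature-table dialect.

    Includes a paired "gene" row per rRNA gene and a handful of CDS
    rows, which a correct parser must ignore.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# " + "\t".join(FEATURE_TABLE_COLUMNS) + "\n")
        for i, g in enumerate(ref.genes):
            base = {c: "" for c in FEATURE_TABLE_COLUMNS}
            base.update(
                {
                    "assembly": "GCF_SYN000001.1",
                    "assembly_unit": "Primary Assembly",
                    "seq_type": "chromosome",
                    "chromosome": g.chromosome,
                    "genomic_accession": f"NC_SYN{g.fasta_header[3:]}",
                    "start": str(g.start),
                    "end": str(g.end),
                    "strand": g.strand,
                    "GeneID": str(1000 + i),
                    "locus_tag": g.gene_id,
                    "feature_interval_length": str(g.length),
                }
            )
            gene_row = dict(base)
            gene_row.update({"feature": "gene", "class": "rRNA", "name": "", "symbol": g.rrna_type})
            fh.write("\t".join(gene_row[c] for c in FEATURE_TABLE_COLUMNS) + "\n")
            rna_row = dict(base)
            rna_row.update(
                {
                    "feature": "rRNA",
                    "class": "rRNA",
                    "name": f"{g.rrna_type} ribosomal RNA",
                    "symbol": g.rrna_type,
                }
            )
            fh.write("\t".join(rna_row[c] for c in FEATURE_TABLE_COLUMNS) + "\n")
        # decoy CDS rows on chr1
        for j in range(5):
            row = {c: "" for c in FEATURE_TABLE_COLUMNS}
            row.update(
                {
                    "feature": "CDS",
                    "class": "with_protein",
                    "chromosome": "1",
                    "start": str(10 + j * 7),
                    "end": str(12 + j * 7),
                    "strand": "+",
                    "locus_tag": f"SYNC_{j:04d}",
                }
            )
            fh.write("\t".join(row[c] for c in FEATURE_TABLE_COLUMNS) + "\n")
    return path


def write_genome_fasta(ref: FixtureReference, path: str | Path) -> Path:
    from rsrnakit.reference import write_fasta

    write_fasta(ref.genome, path)
    return Path(path)


def _draw_locus(
    rng: random.Random, category: str, gene_length: int, length_range: tuple[int, int]
) -> tuple[int, int]:
    lo, hi = length_range
    hi = min(hi, gene_length - 1)  # keep single-end anchoring unambiguous
    length = rng.randint(lo, hi)
    if category == "rRF-5":
        return 1, length
    if category == "rRF-3":
        return gene_length - length + 1, gene_length
    start = rng.randint(2, gene_length - length)
    return start, start + length - 1


def simulate_reads(spec: FixtureSpec, ref: FixtureReference) -> FixtureTruth:
    """Draw reads from rRF positions (plus decoys/ambiguous) with truth.

    Per read: category ~ ``category_fractions``; gene uniform; locus
    from a small per-(gene, category) pool with harmonic weights so a
    few loci dominate, as in real fragment populations. Substitution
    errors are Binomial(read length, ``mismatch_rate``) capped at
    ``max_mismatches``. Every ``minor_variant_every``-th locus pool
    entry carries a designated co-located single-substitution minor
    variant drawn with probability ``minor_variant_prob``.
    """
    rng = random.Random(spec.seed + 1)
    categories = ("rRF-5", "rRF-3", "rRF-i")

    pools: dict[tuple[str, str], list[tuple[int, int]]] = {}
    minor_flags: dict[tuple[str, str, int], bool] = {}
    pool_idx = 0
    for g in ref.genes:
        for cat in categories:
            seen: set[tuple[int, int]] = set()
            pool: list[tuple[int, int]] = []
            attempts = 0
            while len(pool) < spec.loci_per_gene_category and attempts < 200:
                attempts += 1
                locus = _draw_locus(rng, cat, g.length, spec.read_length_range)
                if locus in seen:
                    continue
                seen.add(locus)
                pool.append(locus)
                pool_idx += 1
                minor_flags[(g.gene_id, cat, len(pool) - 1)] = bool(
                    spec.minor_variant_every
                    and pool_idx % spec.minor_variant_every == 0
                )
            pools[(g.gene_id, cat)] = pool

    n_decoy = round(spec.frac_decoy * spec.n_reads)
    n_ambiguous = round(spec.frac_ambiguous * spec.n_reads)
    n_rrna = spec.n_reads - n_decoy - n_ambiguous

    genes_by_id = {g.gene_id: g for g in ref.genes}
    reads: list[SimRead] = []
    kinds = ["rrna"] * n_rrna + ["ambiguous"] * n_ambiguous + ["decoy"] * n_decoy
    rng.shuffle(kinds)

    for i, kind in enumerate(kinds):
        read_id = f"r{i:06d}"
        if kind == "decoy":
            reads.append(_make_decoy(rng, spec, ref, read_id))
            continue
        cat = rng.choices(categories, weights=spec.category_fractions)[0]
        gene = ref.genes[rng.randrange(len(ref.genes))]
        pool = pools[(gene.gene_id, cat)]
        idx = rng.choices(
            range(len(pool)), weights=[1 / (k + 1) for k in range(len(pool))]
        )[0]
        gstart, gend = pool[idx]
        transcript = ref.transcripts[gene.gene_id]
        fragment = transcript[gstart - 1 : gend]

        if minor_flags.get((gene.gene_id, cat, idx)) and rng.random() < spec.minor_variant_prob:
            # designated minor variant: deterministic substitution mid-fragment
            pos = len(fragment) // 2
            aligned = (
                fragment[:pos]
                + _other_base(fragment[pos])
                + fragment[pos + 1 :]
            )
            n_mis = 1
        else:
            n_mis = min(
                sum(1 for _ in range(len(fragment)) if rng.random() < spec.mismatch_rate),
                spec.max_mismatches,
            )
            aligned = _inject_mismatches(rng, fragment, n_mis)

        sense = not (spec.antisense_fraction and rng.random() < spec.antisense_fraction)
        seq = aligned if sense else str(Seq(aligned).reverse_complement())
        if spec.out_of_range_fraction and rng.random() < spec.out_of_range_fraction:
            # out-of-range negative control: truncate to 15 nt at the anchor
            gend = gstart + 14
            aligned = transcript[gstart - 1 : gend]
            seq = aligned if sense else str(Seq(aligned).reverse_complement())
            n_mis = 0
        reads.append(
            SimRead(
                read_id=read_id,
                sequence=seq,
                kind=kind,
                gene_id=gene.gene_id,
                category=cat,
                gene_start=gstart,
                gene_end=gend,
                sense=sense,
                n_mismatches=n_mis,
                aligned_seq=aligned,
            )
        )

    truth = FixtureTruth(genes=ref.genes, transcripts=ref.transcripts, reads=reads)
    truth.loci = _tally_truth_loci(truth, genes_by_id, spec)
    return truth


def _other_base(base: str) -> str:
    return {"A": "G", "C": "T", "G": "A", "T": "C"}[base]


def _inject_mismatches(rng: random.Random, fragment: str, n: int) -> str:
    if n == 0:
        return fragment
    positions = rng.sample(range(len(fragment)), n)
    chars = list(fragment)
    for p in positions:
        choices = [b for b in _BASES if b != chars[p]]
        chars[p] = rng.choice(choices)
    return "".join(chars)


def _make_decoy(
    rng: random.Random, spec: FixtureSpec, ref: FixtureReference, read_id: str
) -> SimRead:
    headers = [h for h in ref.genome if any(g.fasta_header == h for g in ref.genes)]
    for _ in range(100):
        header = rng.choice(headers)
        seq_len = len(ref.genome[header])
        rlen = rng.randint(*spec.read_length_range)
        start = rng.randint(1, seq_len - rlen + 1)
        end = start + rlen - 1
        inside_gene = any(
            g.fasta_header == header and not (end < g.start or start > g.end)
            for g in ref.genes
        )
        if inside_gene:
            continue
        aligned = ref.genome[header][start - 1 : end]
        sense = rng.random() >= 0.5
        seq = aligned if sense else str(Seq(aligned).reverse_complement())
        return SimRead(
            read_id=read_id,
            sequence=seq,
            kind="decoy",
            gene_id=None,
            category=None,
            gene_start=None,
            gene_end=None,
            sense=sense,
            n_mismatches=0,
            aligned_seq=aligned,
            decoy_header=header,
            decoy_start=start,
        )
    raise RuntimeError("could not place a decoy read outside rRNA space")


def _tally_truth_loci(
    truth: FixtureTruth, genes_by_id: dict[str, RRNAGene], spec: FixtureSpec
) -> list[dict]:
    """Per-locus truth derived from the generated reads themselves.

    Only rRNA-exclusive in-range reads contribute (ambiguous reads are
    dropped by the exclusivity rule, decoys never reach a locus). The
    representative is the most frequent sequence; ties break by fewer
    mismatches then lexicographic order.
    """
    lo, hi = 16, 40
    groups: dict[tuple[str, int, int, bool], list[SimRead]] = defaultdict(list)
    for r in truth.reads:
        if r.kind != "rrna":
            continue
        if not (lo <= len(r.sequence) <= hi):
            continue
        groups[(r.gene_id, r.gene_start, r.gene_end, r.sense)].append(r)
    loci = []
    for (gene_id, gstart, gend, sense), members in sorted(groups.items()):
        gene = genes_by_id[gene_id]
        seq_counts = Counter(m.sequence for m in members)
        min_mis = {
            s: min(m.n_mismatches for m in members if m.sequence == s)
            for s in seq_counts
        }
        rep = min(seq_counts, key=lambda s: (-seq_counts[s], min_mis[s], s))
        loci.append(
            {
                "gene_id": gene_id,
                "category": _truth_category(gstart, gend, gene.length),
                "gene_start": gstart,
                "gene_end": gend,
                "sense": sense,
                "count": len(members),
                "sequence": rep,
                "seq_count": seq_counts[rep],
            }
        )
    return loci


def _truth_category(start: int, end: int, length: int) -> str:
    # independent restatement of the positional rule for truth labeling
    if start == 1:
        return "rRF-5"
    if end == length:
        return "rRF-3"
    return "rRF-i"


def write_fastq(truth: FixtureTruth, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for r in truth.reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
    return path


def write_truth_tables(truth: FixtureTruth, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes_path = outdir / "truth_genes.tsv"
    with genes_path.open("w") as fh:
        fh.write("gene_id\tfasta_header\tstart\tend\tstrand\trrna_type\torigin\n")
        for g in truth.genes:
            fh.write(
                f"{g.gene_id}\t{g.fasta_header}\t{g.start}\t{g.end}\t"
                f"{g.strand}\t{g.rrna_type}\t{g.origin}\n"
            )
    reads_path = outdir / "truth_reads.tsv"
    with reads_path.open("w") as fh:
        fh.write(
            "read_id\tkind\tgene_id\tcategory\tgene_start\tgene_end\t"
            "sense\tn_mismatches\n"
        )
        for r in truth.reads:
            fh.write(
                f"{r.read_id}\t{r.kind}\t{r.gene_id or '.'}\t{r.category or '.'}\t"
                f"{r.gene_start or '.'}\t{r.gene_end or '.'}\t"
                f"{'+' if r.sense else '-'}\t{r.n_mismatches}\n"
            )
    loci_path = outdir / "truth_loci.tsv"
    with loci_path.open("w") as fh:
        fh.write(
            "gene_id\tcategory\tgene_start\tgene_end\tsense\tcount\t"
            "sequence\tseq_count\n"
        )
        for l in truth.loci:
            fh.write(
                f"{l['gene_id']}\t{l['category']}\t{l['gene_start']}\t"
                f"{l['gene_end']}\t{'+' if l['sense'] else '-'}\t{l['count']}\t"
                f"{l['sequence']}\t{l['seq_count']}\n"
            )
    return {"genes": genes_path, "reads": reads_path, "loci": loci_path}


def simulate_alignments(
    truth: FixtureTruth,
    ref: FixtureReference,
    masked_genome: dict[str, str] | None = None,
) -> str:
    """Render the truth placements as SAM text (no heuristic alignment).

    The header declares every rRNA transcript and every genome
    sequence. rRNA-space reads get one record against their transcript;
    ambiguous reads additionally get a genomic record outside rRNA
    space; decoys get a single genomic record. NM/MD reflect the
    injected substitutions exactly.
    """
    genome = masked_genome or ref.genome
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for g in truth.genes:
        lines.append(f"@SQ\tSN:{g.gene_id}\tLN:{g.length}")
    for header, seq in genome.items():
        lines.append(f"@SQ\tSN:{header}\tLN:{len(seq)}")
    lines.append("@PG\tID:sim\tPN:rsrnakit-sim")

    # Deterministic non-rRNA placements for ambiguous extras: cycle through
    # the first intergenic gap (always >= 80 nt before the first gene), so a
    # <= 40 nt record can never be contained in an rRNA interval.
    ambiguous_counter = 0
    for r in truth.reads:
        if r.kind == "decoy":
            flag = 0 if r.sense else 16
            seq = r.aligned_seq
            lines.append(
                _sam_line(r.read_id, flag, r.decoy_header, r.decoy_start, seq, 0, nh=1)
            )
            continue
        transcript = truth.transcripts[r.gene_id]
        ref_frag = transcript[r.gene_start - 1 : r.gene_end]
        nh = 2 if r.kind == "ambiguous" else 1
        flag = 0 if r.sense else 16
        lines.append(
            _sam_line(
                r.read_id,
                flag,
                r.gene_id,
                r.gene_start,
                r.aligned_seq,
                r.n_mismatches,
                nh=nh,
                md=_md_string(ref_frag, r.aligned_seq),
            )
        )
        if r.kind == "ambiguous":
            # secondary placement in non-rRNA genome space
            header = next(iter(genome))
            pos = 1 + (ambiguous_counter % 30)
            ambiguous_counter += 1
            lines.append(
                _sam_line(
                    r.read_id,
                    flag | 256,
                    header,
                    pos,
                    r.aligned_seq,
                    r.n_mismatches,
                    nh=nh,
                )
            )
    return "\n".join(lines) + "\n"


def _sam_line(
    read_id: str,
    flag: int,
    rname: str,
    pos: int,
    seq: str,
    nm: int,
    nh: int,
    md: str | None = None,
) -> str:
    fields = [
        read_id,
        str(flag),
        rname,
        str(pos),
        "255",
        f"{len(seq)}M",
        "*",
        "0",
        "0",
        seq,
        "I" * len(seq),
        f"NM:i:{nm}",
        f"NH:i:{nh}",
    ]
    if md is not None:
        fields.append(f"MD:Z:{md}")
    return "\t".join(fields)


def _md_string(ref_frag: str, aligned: str) -> str:
    """MD tag for a gapless alignment of ``aligned`` against ``ref_frag``."""
    out: list[str] = []
    run = 0
    for a, b in zip(ref_frag, aligned):
        if a == b:
            run += 1
        else:
            out.append(str(run))
            out.append(a)
            run = 0
    out.append(str(run))
    return "".join(out)


def write_sam(
    truth: FixtureTruth,
    ref: FixtureReference,
    path: str | Path,
    masked_genome: dict[str, str] | None = None,
) -> Path:
    path = Path(path)
    path.write_text(simulate_alignments(truth, ref, masked_genome))
    return path
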