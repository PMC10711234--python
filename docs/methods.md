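# Methods

## Problem and model

Small-RNA sequencing libraries contain large numbers of rRNA-derived
fragments (rsRNAs). Two properties make them hard to annotate with generic
small-RNA tools: rRNA genes are highly repetitive (so rRNA reads multi-map
across the genome), and the fragments are produced positionally (5′-anchored,
3′-anchored, or internal) from a small set of parental transcripts.

`rsrnakit` addresses the first problem by construction. The reference the
reads are aligned against is the concatenation of (a) an *artificial
genome* in which every annotated rRNA gene, optionally extended by a flank,
is replaced by `N`, and (b) the rRNA transcript sequences extracted
strand-aware from the unmasked genome (position 1 of each extracted record
is the transcript 5′ end). With rRNA sequence removed from the genome, any
alignment to remaining genome space is evidence of non-rRNA origin.
`rsrnakit` consumes the resulting SAM; it does not run the aligner itself.
Alignment stringency defaults mirror common short-read settings for this
task (at most 50 reported alignments per read; per-alignment edit distance
kept as the `Difference` statistic).

**Exclusivity rule.** A read is retained iff *all* of its reported
alignments fall in rRNA space (a transcript reference, or wholly inside an
annotated rRNA interval ± the configured flank). Reads with a mixture of
rRNA and genome alignments are counted as *ambiguous* and dropped; reads
with only genome alignments are *non-rRNA*. The three classes partition the
read ids exactly, and the partition is reported per sample. Only the
annotated rRNA interval (± flank) counts as rRNA space; unannotated
spacer/ETS regions do not.

**Classification.** With transcript coordinates (1-based, 5′ end = 1):
start = 1 → `rRF-5`; end = transcript length (and start > 1) → `rRF-3`;
otherwise `rRF-i`. A full-span read satisfies both end rules; it is
assigned `rRF-5` by default (configurable through
`classify_rrf(full_span_category=...)`), consistent with the 5′ skew
reported for rsRNA populations. These rules are total and mutually
exclusive over all intervals of a transcript. Antisense reads (read strand
opposite the transcript) are classified by the same positional rules and
carried with `sense=False`, but are excluded from the headline outputs by
default (`include_antisense` flips this).

**Quantification.** Reads are aggregated by (gene, transcript start,
transcript end, sense). The locus representative is the most frequent
unique sequence; ties break toward the lower edit distance and then
lexicographically, which makes output deterministic. Abundance is
RPM = count / library_total × 10⁶. The denominator defaults to the number
of reads in the trimmed FASTQ when present, else the number of distinct
read ids in the SAM.

**Confidence filters.** `Difference < 4` (strict, i.e. 0–3 mismatches +
indel bases) and `RPM ≥ 10` (inclusive), both configurable. A separate
`max_mismatch_rate` knob (default 5%) is exposed for aligner-level
stringency but is not applied post hoc. Entries co-located at identical
genomic (start, end, strand) are folded into the most abundant one before
the RPM test: the minor entries disappear as records but their reads stay
in the survivor's `count`, so per-gene read counts are conserved.
"Co-located" deliberately means *identical* coordinates, not any overlap —
overlapping-but-distinct loci are biologically distinct fragment species.

**Structure column.** The HTML report adds a dot-bracket column computed by
Nussinov base-pair maximization (pairs AU, GC, GU; minimum hairpin loop of
3 unpaired bases). For ≤ 40-nt fragments this is a deterministic structural
sketch, not a thermodynamic prediction; `fold_dot_bracket(folder=...)`
accepts an external folder (e.g. a ViennaRNA wrapper) as a drop-in
replacement. The traceback prefers the pairing that closes earliest
(leftmost 5′ partner, nearest legal 3′ partner), so co-optimal structures
resolve identically on every run.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `flank` | 0 nt | extension of masked/rRNA-space intervals |
| `max_difference` | 4 (exclusive) | mismatches + inserted + deleted bases |
| `min_rpm` | 10 (inclusive) | minimum locus abundance |
| `length_min`/`length_max` | 16 / 40 nt | inclusive fragment length range |
| `max_hits` | 50 | multimap cap; beyond it a read is flagged |
| `top_n_abundance` | 5 | rows per rRNA type in the abundance summary |

Boundary semantics (4 out / 3 in; 10.0 in / 9.99 out; 15 and 41 out, 16 and
40 in) are unit-tested.

## Pipeline mechanics

Stages run as reference → filter → classify → report, per sample. Each
stage records SHA-256 digests of its input files plus a parameter hash in
`intermediate/<genome>/manifest.json`; a stage re-runs only when an output
is missing or a digest/parameter changed (content, not timestamps, so
copies stay fresh). Stages write into scratch space and move outputs
atomically — a failed stage leaves no partial file at a final path. Two
consecutive runs on unchanged inputs are byte-identical, including figures
(the SVG hash salt is pinned and date metadata suppressed). A failing
sample is isolated; other samples still run and the CLI exits non-zero.

## Synthetic data generator

`rsrnakit.simulate` defines the test conditions rather than serving as a
loose fixture. Defaults: seed 42; six rRNA genes — four nuclear on two
chromosomes, one on `chrMt`, one on `chrPt`, strands alternating so both
orientations always occur; 5,000 reads of 16–40 nt; category mix
0.5/0.3/0.2 for rRF-5/rRF-3/rRF-i; zero mismatch rate; no decoy or
ambiguous reads. Gene lengths are drawn from 150–400 nt with 80–200 nt
intergenic gaps: long enough that fragment categories are unambiguous and
loci plentiful, short enough that a full run takes seconds. Reads pick a
category, then a gene, then a locus from a small per-(gene, category) pool
with harmonic weights, so a few loci dominate as in real fragment
populations. Substitution errors are Binomial(length, rate) capped at 3;
designated co-located minor variants (single mid-fragment substitution) can
be injected per locus. Alignments are rendered directly from the truth as
SAM (`<len>M`, exact NM/MD, FLAG 16 for antisense, an extra genome-space
record for ambiguous reads), so the tests exercise the post-alignment logic
and never an aligner re-implementation.

What the generator does **not** emulate: structure-biased fragmentation,
terminal modifications that bias library construction, indels, quality
variation (all qualities are `I`), adapter remnants, and multi-mapping
*within* rRNA space across near-identical rRNA repeats. Passing tests
therefore demonstrate the correctness of the masking/filtering/
classification/quantification logic under controlled origin and error
models — not annotation accuracy on a real repeat-rich genome.

## Numerical and format choices

- All coordinates are 1-based inclusive internally (feature table and SAM
  conventions); only the mask-log BED is 0-based half-open.
- The masking character is `N`, the alignment-neutral convention.
- Feature-table parsing uses rows with `feature == "rRNA"` only; paired
  "gene" rows would double-count the same interval. Chromosome labels map
  to FASTA headers by stripping a case-insensitive `chr` prefix, sending
  mitochondrial aliases (`MT`, `mitochondrion`, …) to `chrMt` and plastid
  aliases (`Pltd`, `chloroplast`, …) to `chrPt`, integers to `chr<n>`;
  the mapping is user-overridable (`header_map`) because NCBI labels vary.
  Header validation accepts zero-padded integers (`chr02`).
- The annotation CSV reproduces its column order and header spellings
  verbatim as a stable contract — including the inconsistent
  `Gene_Start` / `Gene End` pair — with RPM at 2 decimals. The abundance
  summary's eight columns are fixed as rRNA_type, origin, Category,
  Sequence, Length, RPM, Seq_count, count.
- NM is trusted over recomputation when present; otherwise differences are
  reconstructed from MD + CIGAR (soft clips never count). With neither tag
  and ambiguous `M` operations, the difference is declared undeterminable
  rather than guessed.
- Genomic reads hanging over a transcript boundary have no defined
  category and are dropped with a warning.

## Known limitations

- RPM does not support cross-library comparison; no cross-sample
  normalization or differential analysis is provided.
- Reference-dependent: annotation quality is bounded by the feature table's
  rRNA annotation.
- The low-abundance co-location rule folds whole groups at identical
  coordinates; overlap-based deduplication is intentionally out of scope.
- The HTML report is static; no interactive exploration.
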