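"""Positional classification, locus aggregation, RPM and confidence filters."""

import random

import pytest

from rsrnakit.classify import (
    ClassifiedRead,
    LibraryContext,
    aggregate_loci,
    annotate_modification_overlap,
    classify_reads,
    classify_rrf,
    compute_rpm,
    filter_confident,
    length_filter,
)
from rsrnakit.alignment import AlignedRead
from rsrnakit.reference import RRNAGene

GENE = RRNAGene(
    gene_id="g1", chromosome="1", fasta_header="chr1",
    start=1001, end=1200, strand="+", rrna_type="18S",
)


def _cread(gene_start, gene_end, seq=None, diff=0, sense=True, read_id="r", gene_id="g1"):
    seq = seq if seq is not None else "A" * (gene_end - gene_start + 1)
    cat = classify_rrf(gene_start, gene_end, GENE.length)
    return ClassifiedRead(
        read_id=read_id, gene_id=gene_id, gene_start=gene_start,
        gene_end=gene_end, sense=sense, sequence=seq, difference=diff, category=cat,
    )


class TestClassifyRrf:
    @pytest.mark.parametrize(
        ("interval", "expected"),
        [((1, 24, 1808), "rRF-5"), ((1785, 1808, 1808), "rRF-3"),
         ((50, 70, 1808), "rRF-i"), ((1, 1808, 1808), "rRF-5")],
    )
    def test_examples(self, interval, expected):
        assert classify_rrf(*interval) == expected

    def test_full_span_category_is_configurable(self):
        assert classify_rrf(1, 100, 100, full_span_category="rRF-3") == "rRF-3"

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            classify_rrf(0, 10, 100)
        with pytest.raises(ValueError):
            classify_rrf(5, 101, 100)

    def test_brute_force_interval_census(self):
        """All intervals of a length-L transcript map to exactly one category
        and the three categories census to L(L+1)/2."""
        L = 20
        counts = {"rRF-5": 0, "rRF-3": 0, "rRF-i": 0}
        for s in range(1, L + 1):
            for e in range(s, L + 1):
                counts[classify_rrf(s, e, L)] += 1
        assert sum(counts.values()) == L * (L + 1) // 2 == 210
        # forced by the rule: L intervals start at 1; L-1 end at L without
        # starting at 1; the rest are internal
        assert counts["rRF-5"] == L
        assert counts["rRF-3"] == L - 1


class TestLengthFilter:
    def test_inclusive_bounds(self):
        reads = [_cread(10, 10 + n - 1) for n in (15, 16, 40, 41)]
        kept = length_filter(reads, (16, 40))
        assert sorted(len(r.sequence) for r in kept) == [16, 40]

    def test_empty_input(self):
        assert length_filter([], (16, 40)) == []


class TestAggregateLoci:
    def test_majority_sequence_wins(self):
        reads = [_cread(10, 13, seq="AAAA", read_id=f"a{i}") for i in range(3)]
        reads += [_cread(10, 13, seq="AAAT", read_id="b0")]
        (locus,) = aggregate_loci(reads, [GENE])
        assert (locus.sequence, locus.seq_count, locus.count) == ("AAAA", 3, 4)

    def test_tie_breaks_toward_lower_difference(self):
        reads = [
            _cread(10, 13, seq="AAAA", diff=0, read_id="a0"),
            _cread(10, 13, seq="AAAA", diff=0, read_id="a1"),
            _cread(10, 13, seq="AAAT", diff=1, read_id="b0"),
            _cread(10, 13, seq="AAAT", diff=1, read_id="b1"),
        ]
        (locus,) = aggregate_loci(reads, [GENE])
        assert locus.sequence == "AAAA"

    def test_count_conservation_on_fixture(self, fixture_ref, fixture_truth):
        """Sum of locus counts per gene equals retained classified reads per gene."""
        from rsrnakit.alignment import AlignedRead

        alns = [
            AlignedRead(
                read_id=r.read_id, sequence=r.sequence, target_id=r.gene_id,
                target_start=r.gene_start, target_end=r.gene_end,
                strand="+" if r.sense else "-", difference=r.n_mismatches,
            )
            for r in fixture_truth.reads if r.kind == "rrna"
        ]
        classified = classify_reads(alns, fixture_ref.genes)
        loci = aggregate_loci(classified, fixture_ref.genes)
        per_gene_reads = {}
        for r in classified:
            per_gene_reads[r.gene_id] = per_gene_reads.get(r.gene_id, 0) + 1
        per_gene_loci = {}
        for l in loci:
            per_gene_loci[l.gene.gene_id] = per_gene_loci.get(l.gene.gene_id, 0) + l.count
        assert per_gene_loci == per_gene_reads

    def test_representative_matches_truth_with_minor_variants(self):
        from rsrnakit.simulate import FixtureSpec, generate_reference, simulate_reads

        spec = FixtureSpec(seed=11, n_reads=2000, minor_variant_every=3)
        ref = generate_reference(spec)
        truth = simulate_reads(spec, ref)
        alns = [
            AlignedRead(
                read_id=r.read_id, sequence=r.sequence, target_id=r.gene_id,
                target_start=r.gene_start, target_end=r.gene_end,
                strand="+" if r.sense else "-", difference=r.n_mismatches,
            )
            for r in truth.reads if r.kind == "rrna"
        ]
        loci = aggregate_loci(classify_reads(alns, ref.genes), ref.genes)
        got = {
            (l.gene.gene_id, l.gene_start, l.gene_end, l.sense): (l.sequence, l.seq_count, l.count)
            for l in loci
        }
        assert any(len(l.seq_counts) > 1 for l in loci), "no minor variants injected"
        for t in truth.loci:
            key = (t["gene_id"], t["gene_start"], t["gene_end"], t["sense"])
            assert got[key] == (t["sequence"], t["seq_count"], t["count"])


class TestComputeRpm:
    @pytest.mark.parametrize(
        ("count", "total", "expected"),
        [(0, 1_000_000, 0.0), (25, 2_000_000, 12.5), (10, 1_000_000, 10.0)],
    )
    def test_examples(self, count, total, expected):
        assert compute_rpm(count, total) == expected

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            compute_rpm(5, 0)

    def test_linearity_under_joint_doubling(self):
        rng = random.Random(3)
        for _ in range(200):
            c = rng.randint(0, 10_000)
            t = rng.randint(1, 10_000_000)
            assert compute_rpm(2 * c, 2 * t) == compute_rpm(c, t)


class TestFilterConfident:
    def _ctx(self, total=1_000_000):
        return LibraryContext(library_total=total)

    def test_difference_boundary_is_strict(self):
        loci = aggregate_loci(
            [_cread(10, 30, diff=4, read_id=f"r{i}") for i in range(20)], [GENE]
        )
        assert filter_confident(loci, self._ctx(total=1000)) == []
        loci = aggregate_loci(
            [_cread(10, 30, diff=3, read_id=f"r{i}") for i in range(20)], [GENE]
        )
        assert len(filter_confident(loci, self._ctx(total=1000))) == 1

    def test_rpm_boundary_is_inclusive(self):
        # 10 reads in a million-read library: exactly 10.0 RPM -> retained
        loci = aggregate_loci(
            [_cread(10, 30, read_id=f"r{i}") for i in range(10)], [GENE]
        )
        (rec,) = filter_confident(loci, self._ctx())
        assert rec.rpm == 10.0
        # 9 reads: 9.0 RPM -> excluded
        loci = aggregate_loci(
            [_cread(10, 30, read_id=f"r{i}") for i in range(9)], [GENE]
        )
        assert filter_confident(loci, self._ctx()) == []

    def test_colocated_minor_folds_into_major(self):
        """Antisense locus at the same genomic footprint stays separate; a
        low-abundance co-located (same coords, same strand) entry is folded."""
        minus_gene = RRNAGene(
            gene_id="g2", chromosome="1", fasta_header="chr1",
            start=1001, end=1200, strand="-", rrna_type="25S",
        )
        # same genomic interval 1011..1030 seen through g1(+) and through
        # g2(-) antisense (read strand +), so strand matches: co-located
        major = [_cread(11, 30, read_id=f"a{i}") for i in range(50)]
        minor_reads = [
            ClassifiedRead(
                read_id=f"b{i}", gene_id="g2", gene_start=171, gene_end=190,
                sense=False, sequence="C" * 20, difference=0, category="rRF-i",
            )
            for i in range(2)
        ]
        loci = aggregate_loci(major + minor_reads, [GENE, minus_gene])
        ctx = LibraryContext(library_total=1_000_000)
        records = filter_confident(loci, ctx, include_antisense=True)
        (rec,) = records
        assert rec.count == 52 and rec.seq_count == 50
        assert rec.rpm == compute_rpm(52, 1_000_000)

    def test_antisense_excluded_by_default(self):
        reads = [_cread(10, 30, sense=False, read_id=f"r{i}") for i in range(50)]
        loci = aggregate_loci(reads, [GENE])
        assert filter_confident(loci, self._ctx(total=1000)) == []
        assert len(filter_confident(loci, self._ctx(total=1000), include_antisense=True)) == 1


class TestModificationOverlap:
    def test_boundary_containment(self):
        reads = [_cread(10, 30, read_id=f"r{i}") for i in range(20)]
        loci = aggregate_loci(reads, [GENE])
        (rec,) = filter_confident(loci, LibraryContext(library_total=1000))
        sites = [("g1", 20, "methylation"), ("g1", 31, "pseudouridylation"),
                 ("g1", 10, "methylation"), ("g1", 30, "pseudouridylation")]
        per_record, totals = annotate_modification_overlap([rec], sites)
        assert len(per_record[0]) == 3
        assert totals == {"methylation": 2, "pseudouridylation": 1}

    def test_site_outside_gene_is_skipped(self, caplog):
        reads = [_cread(10, 30, read_id=f"r{i}") for i in range(20)]
        loci = aggregate_loci(reads, [GENE])
        (rec,) = filter_confident(loci, LibraryContext(library_total=1000))
        with caplog.at_level("WARNING"):
            _, totals = annotate_modification_overlap(
                [rec], [("g1", 9999, "methylation")], genes={"g1": GENE}
            )
        assert totals == {}
        assert "skipped" in caplog.text

    def test_counts_match_brute_force_on_fixture(self, fixture_ref, fixture_truth):
        rng = random.Random(5)
        records = []
        for t in fixture_truth.loci[:30]:
            reads = [
                ClassifiedRead(
                    read_id=f"x{i}", gene_id=t["gene_id"], gene_start=t["gene_start"],
                    gene_end=t["gene_end"], sense=True, sequence=t["sequence"],
                    difference=0, category=t["category"],
                )
                for i in range(20)
            ]
            loci = aggregate_loci(reads, fixture_ref.genes)
            records += filter_confident(loci, LibraryContext(library_total=1000))
        genes = {g.gene_id: g for g in fixture_ref.genes}
        sites = [
            (g.gene_id, rng.randint(1, g.length), rng.choice(["methylation", "pseudouridylation"]))
            for g in fixture_ref.genes for _ in range(10)
        ]
        per_record, totals = annotate_modification_overlap(records, sites, genes=genes)
        brute = {}
        for rec, hits in zip(records, per_record):
            expected = [
                s for s in sites
                if s[0] == rec.gene_id and rec.gene_start <= s[1] <= rec.gene_end
            ]
            assert hits == expected
            for s in expected:
                brute[s[2]] = brute.get(s[2], 0) + 1
        assert totals == brute
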