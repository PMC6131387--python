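"""Gene coverage, operon-variant enumeration and context counting."""

import numpy as np
import pytest

from opvar.formats_io import AlignedReadRecord, AnnotatedOperon, GeneRecord
from opvar.operon_builder import (
    OperonVariant,
    TranscriptUnit,
    build_operons,
    compare_contexts,
    count_contexts,
    find_antisense_operons,
    find_extended_operons,
    genes_fully_covered,
    reduce_to_maximal,
)
from opvar.tss_calling import TSSCluster
from opvar.tts_calling import TTSCall
from conftest import make_library, make_read


def cluster(pos, strand="+", members=None):
    return TSSCluster("chr1", pos, strand, tuple(members or (pos,)), 100)


def tts(pos, strand="+"):
    return TTSCall("chr1", pos, strand, (0,), 20, 100, pos + 1, 0.2, 1e-9)


class TestGenesFullyCovered:
    def test_partial_coverage_excluded(self, three_gene_annotation):
        read = make_read("r", 100, 1000)
        assert genes_fully_covered(read, three_gene_annotation) == ("geneA", "geneB")

    def test_strand_aware(self, three_gene_annotation):
        genes = list(three_gene_annotation)
        genes[1] = GeneRecord("geneB", "chr1", 500, 900, "-")
        assert genes_fully_covered(make_read("r", 100, 1000), genes) == ("geneA",)

    def test_no_gene_covered(self, three_gene_annotation):
        assert genes_fully_covered(make_read("r", 0, 120), three_gene_annotation) == ()

    def test_minus_strand_ordered_five_to_three(self):
        genes = [
            GeneRecord("a", "chr1", 100, 200, "-"),
            GeneRecord("b", "chr1", 300, 400, "-"),
        ]
        read = make_read("r", 50, 450, "-")
        assert genes_fully_covered(read, genes) == ("b", "a")


class TestBuildOperons:
    def test_hand_grouping_example(self, three_gene_annotation):
        # 12 reads stop at a TTS after genes A,B; 8 read through to cover A,B,C
        reads = [make_read(f"t{i}", 100, 931, "+") for i in range(12)]
        reads += [make_read(f"l{i}", 100, 1301, "+") for i in range(8)]
        variants = build_operons(
            reads, [cluster(100)], [tts(930)], three_gene_annotation
        )
        by_tuple = {v.gene_ids: v for v in variants}
        assert set(by_tuple) == {("geneA", "geneB"), ("geneA", "geneB", "geneC")}
        assert by_tuple[("geneA", "geneB")].total_support == 12
        assert by_tuple[("geneA", "geneB")].units[0].end_is_tts
        assert by_tuple[("geneA", "geneB", "geneC")].total_support == 8
        assert not by_tuple[("geneA", "geneB", "geneC")].units[0].end_is_tts

    def test_reads_covering_no_gene_dropped(self, three_gene_annotation):
        reads = [make_read(f"r{i}", 100, 140, "+") for i in range(6)]
        assert build_operons(reads, [cluster(100)], [], three_gene_annotation) == []

    def test_two_tss_same_tuple_merge_into_one_variant(self, three_gene_annotation):
        reads = [make_read(f"a{i}", 100, 931, "+") for i in range(6)]
        reads += [make_read(f"b{i}", 120, 931, "+") for i in range(4)]
        variants = build_operons(
            reads, [cluster(100), cluster(120)], [tts(930)], three_gene_annotation
        )
        (v,) = variants
        assert v.gene_ids == ("geneA", "geneB")
        assert len(v.units) == 2 and v.total_support == 10

    def test_rrna_genes_excluded_by_default(self):
        genes = [
            GeneRecord("cds", "chr1", 150, 300, "+"),
            GeneRecord("rib", "chr1", 400, 600, "+", biotype="rRNA"),
        ]
        reads = [make_read(f"r{i}", 100, 700, "+") for i in range(5)]
        (v,) = build_operons(reads, [cluster(100)], [], genes)
        assert v.gene_ids == ("cds",)
        (v2,) = build_operons(reads, [cluster(100)], [], genes, exclude_rrna=False)
        assert v2.gene_ids == ("cds", "rib")

    def test_support_conservation(self, sim_dataset):
        """Total variant support equals reads with a retained TSS and genes."""
        import opvar
        from opvar.tss_calling import assign_reads_to_clusters
        from opvar.tts_calling import call_tts as _call, merge_tts, tally_three_prime_ends

        tss = opvar.call_tss(sim_dataset["enriched"], sim_dataset["control"])
        calls = merge_tts(_call(tally_three_prime_ends(sim_dataset["enriched"], tss)))
        genes = sim_dataset["genes"]
        variants = build_operons(sim_dataset["enriched"], tss, calls, genes)
        total = sum(v.total_support for v in variants)
        expected = sum(
            1
            for u in (
                unit for v in variants for unit in v.units
            )
            for _ in range(u.support)
        )
        assert total == expected
        # and support is bounded by the reads assigned to retained TSSs
        assigned = assign_reads_to_clusters(sim_dataset["enriched"].reads, tss)
        assert total <= sum(len(v) for v in assigned.values())

    def test_matches_exhaustive_enumeration_on_random_instances(self):
        """Oracle: unique fully-covered gene tuples per (TSS, end) group."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n_genes = rng.integers(1, 9)
            genes = []
            pos = 0
            for g in range(n_genes):
                start = pos + int(rng.integers(5, 30))
                end = start + int(rng.integers(20, 120))
                strand = "+" if rng.random() < 0.7 else "-"
                genes.append(GeneRecord(f"g{g}", "chr1", start, end, strand))
                pos = end
            tss_positions = sorted(
                int(p) for p in rng.choice(pos, size=2, replace=False)
            )
            clusters = [cluster(p) for p in tss_positions]
            tts_calls = [tts(int(rng.integers(50, pos + 50)))]
            reads = []
            for i in range(int(rng.integers(1, 31))):
                start = int(rng.choice(tss_positions))
                end = start + int(rng.integers(10, pos + 100 - start))
                reads.append(make_read(f"r{i}", start, end, "+"))
            got = build_operons(reads, clusters, tts_calls, genes)
            expected = _oracle_operons(reads, clusters, tts_calls, genes)
            assert {
                (v.gene_ids, v.strand): v.total_support for v in got
            } == expected


def _oracle_operons(reads, clusters, tts_calls, genes, window=5):
    """Brute-force re-derivation: group reads, take tuple over group span."""
    member_of = {
        (c.chrom, m, c.strand): c for c in clusters for m in c.members
    }
    groups = {}
    for r in reads:
        c = member_of.get((r.chrom, r.five_prime, r.strand))
        if c is None:
            continue
        near = [
            t.position
            for t in tts_calls
            if t.strand == c.strand and abs(t.position - r.three_prime) <= window
        ]
        key = (c, min(near, key=lambda p: abs(p - r.three_prime)) if near else None)
        groups.setdefault(key, []).append(r)
    support = {}
    for (c, tts_pos), rs in groups.items():
        if tts_pos is None:
            end = (
                max(r.three_prime for r in rs)
                if c.strand == "+"
                else min(r.three_prime for r in rs)
            )
        else:
            end = tts_pos
        lo, hi = sorted((c.position, end))
        covered = [
            g
            for g in genes
            if g.strand == c.strand and g.biotype.lower() != "rrna"
            and lo <= g.start and g.end <= hi + 1
        ]
        covered.sort(key=lambda g: g.start, reverse=c.strand == "-")
        tup = tuple(g.gene_id for g in covered)
        if tup:
            support[(tup, c.strand)] = support.get((tup, c.strand), 0) + len(rs)
    return support


class TestExtendedOperons:
    G = [
        GeneRecord("a", "chr1", 100, 300, "+"),
        GeneRecord("b", "chr1", 400, 700, "+"),
        GeneRecord("c", "chr1", 800, 1100, "+"),
    ]

    def test_downstream_extension_detected(self):
        annotated = [AnnotatedOperon("op1", ("a", "b"), "+")]
        reads = [make_read("r", 50, 1200, "+")]
        (rep,) = find_extended_operons(reads, annotated, self.G)
        assert rep.extended and rep.sides == ("3'",) and rep.extra_genes == ("c",)

    def test_sub_operon_removed_before_testing(self):
        annotated = [
            AnnotatedOperon("sub", ("a", "b"), "+"),
            AnnotatedOperon("full", ("a", "b", "c"), "+"),
        ]
        reads = [make_read("r", 50, 1200, "+")]
        reports = find_extended_operons(reads, annotated, self.G)
        assert [r.operon.operon_id for r in reports] == ["full"]
        assert not reports[0].extended  # no gene beyond the full operon

    def test_partial_coverage_is_not_extension(self):
        annotated = [AnnotatedOperon("op1", ("a", "b"), "+")]
        reads = [make_read("r", 50, 350, "+")]  # covers a only
        (rep,) = find_extended_operons(reads, annotated, self.G)
        assert not rep.extended

    def test_upstream_side_recorded(self):
        annotated = [AnnotatedOperon("op1", ("b", "c"), "+")]
        reads = [make_read("r", 50, 1200, "+")]
        (rep,) = find_extended_operons(reads, annotated, self.G)
        assert rep.extended and rep.sides == ("5'",)

    def test_unknown_gene_skipped_with_warning(self):
        annotated = [AnnotatedOperon("op1", ("a", "ghost"), "+")]
        with pytest.warns(UserWarning, match="absent"):
            assert find_extended_operons([], annotated, self.G) == []

    def test_matches_brute_force_subset_logic(self):
        rng = np.random.default_rng(3)
        genes = [
            GeneRecord(f"g{i}", "chr1", 100 * i, 100 * i + 60, "+") for i in range(8)
        ]
        for _ in range(200):
            n_ops = int(rng.integers(1, 5))
            annotated = []
            for j in range(n_ops):
                k = int(rng.integers(1, 5))
                lo = int(rng.integers(0, 8 - k + 1))
                annotated.append(
                    AnnotatedOperon(f"op{j}", tuple(f"g{i}" for i in range(lo, lo + k)), "+")
                )
            reads = [
                make_read(f"r{i}", int(s), int(s) + int(rng.integers(80, 700)), "+")
                for i, s in enumerate(rng.integers(0, 700, size=rng.integers(1, 10)))
            ]
            got = {
                r.operon.operon_id: r.extended
                for r in find_extended_operons(reads, annotated, genes)
            }
            # oracle: explicit subset logic
            maximal = [
                op
                for op in annotated
                if not any(
                    o is not op and set(op.gene_ids) < set(o.gene_ids)
                    for o in annotated
                )
            ]
            seen = set()
            expected = {}
            for op in maximal:
                if frozenset(op.gene_ids) in seen:
                    continue
                seen.add(frozenset(op.gene_ids))
                ext = False
                for r in reads:
                    covered = {
                        g.gene_id
                        for g in genes
                        if r.start <= g.start and g.end <= r.end
                    }
                    if set(op.gene_ids) <= covered and covered - set(op.gene_ids):
                        ext = True
                expected[op.operon_id] = ext
            assert got == expected


class TestContexts:
    def variant(self, ids, support=5):
        unit = TranscriptUnit(cluster(0), 100, False, tuple(ids), support)
        return OperonVariant(tuple(ids), "+", "chr1", (unit,), support)

    def test_context_counting(self):
        variants = [self.variant(t) for t in [("a", "x"), ("x",), ("x", "b")]]
        records = {r.gene_id: r for r in count_contexts(variants)}
        assert records["x"].n_contexts == 3
        assert records["a"].n_contexts == 1
        assert "absent" not in records

    def test_eight_context_gene(self):
        """A gene carried by eight distinct variants reports eight contexts."""
        combos = [
            ("g1", "g2", "g3", "frr"), ("g2", "g3", "frr", "g5"),
            ("g2", "g3", "frr"), ("g3", "frr", "g5"), ("g3", "frr"),
            ("frr", "g5", "g6", "g7"), ("frr", "g5", "g6"), ("frr",),
        ]
        records = {r.gene_id: r for r in count_contexts([self.variant(c) for c in combos])}
        assert records["frr"].n_contexts == 8
        assert len(set(records["frr"].contexts)) == 8

    def test_compare_contexts_outer_join(self):
        a = count_contexts([self.variant(("a", "x")), self.variant(("x",))])
        b = count_contexts([self.variant(("x", "b"))])
        df = compare_contexts(a, b).set_index("gene_id")
        assert df.loc["x", "n_contexts_a"] == 2 and df.loc["x", "n_contexts_b"] == 1
        assert df.loc["a", "n_contexts_b"] == 0
        assert df.loc["b", "n_contexts_a"] == 0

    def test_identical_sets_all_equal(self):
        a = count_contexts([self.variant(("a", "x"))])
        df = compare_contexts(a, a)
        assert (df["n_contexts_a"] == df["n_contexts_b"]).all()


class TestAntisense:
    def test_contained_opposite_gene_qualifies(self):
        genes = [GeneRecord("anti", "chr1", 2000, 2500, "-")]
        unit = TranscriptUnit(cluster(1000), 4999, False, ("x",), 5)
        v = OperonVariant(("x",), "+", "chr1", (unit,), 5)
        assert find_antisense_operons([v], genes) == [v]

    def test_straddling_gene_does_not_qualify(self):
        genes = [GeneRecord("anti", "chr1", 4500, 5600, "-")]
        unit = TranscriptUnit(cluster(1000), 4999, False, ("x",), 5)
        v = OperonVariant(("x",), "+", "chr1", (unit,), 5)
        assert find_antisense_operons([v], genes) == []


def test_reduce_to_maximal_drops_strict_subsets():
    ops = [
        AnnotatedOperon("s", ("a", "b"), "+"),
        AnnotatedOperon("f", ("a", "b", "c"), "+"),
        AnnotatedOperon("other_strand", ("a", "b"), "-"),
    ]
    kept = {o.operon_id for o in reduce_to_maximal(ops)}
    assert kept == {"f", "other_strand"}
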