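"""Method-1/Method-2 calling, tree inference from shared variants, the
pairwise dendrogram, and first-division orientation."""

import pytest

from lineageseq import (
    AlleleCounts,
    CoincidentGroup,
    RawSnv,
    ScoringParams,
    VariantLocus,
    call_method1,
    build_tree_from_sets,
    group_coincident,
    infer_sets,
    orient_root_split,
    pairwise_dendrogram,
)
from lineageseq.calling import CladeFrequencyTable, gap_min_count


SUBCLONES = ["A", "B", "C", "D"]


def het_table(make, carriers, pos=100):
    cells = {(0, s): (15, 15) for s in carriers}
    return make([VariantLocus("chr1", pos, "G", "T")], SUBCLONES, cells)


class TestMethod1:
    def test_planted_clade_assigned(self, quartet_tree, counts_builder):
        table = het_table(counts_builder, ["A", "B"])
        cand = CoincidentGroup(table.loci[0], frozenset({"A", "B"}))
        res = call_method1([cand], table, quartet_tree)
        assert len(res.branch) == 1
        bv = res.branch[0]
        assert bv.clade == frozenset({"A", "B"})
        assert bv.edge_id == "A,B"
        assert bv.quality >= 0.99

    def test_discordant_set_dropped(self, quartet_tree, counts_builder):
        # {A, C} is not a clade of ((A,B),(C,D)): every tree-consistent
        # option leaves one sample badly explained
        table = het_table(counts_builder, ["A", "C"])
        cand = CoincidentGroup(table.loci[0], frozenset({"A", "C"}))
        res = call_method1([cand], table, quartet_tree)
        assert res.branch == [] and res.leaf == []
        assert len(res.discordant) == 1

    def test_singleton_argmax_becomes_leaf(self, quartet_tree, counts_builder):
        table = het_table(counts_builder, ["A"])
        # candidate claims {A,B} but counts only support A
        cand = CoincidentGroup(table.loci[0], frozenset({"A", "B"}))
        res = call_method1([cand], table, quartet_tree)
        assert res.branch == []
        assert len(res.leaf) == 1 and res.leaf[0].subclone_id == "A"

    def test_loh_flagged_out(self, quartet_tree, counts_builder):
        cells = {(0, "A"): (1, 29), (0, "B"): (2, 28)}
        table = counts_builder(
            [VariantLocus("chr1", 100, "G", "T")], SUBCLONES, cells
        )
        cand = CoincidentGroup(table.loci[0], frozenset({"A", "B"}))
        res = call_method1([cand], table, quartet_tree)
        assert res.branch == [] and len(res.loh_flagged) == 1

    def test_missing_subclone_in_tree_errors(self, quartet_tree, counts_builder):
        table = counts_builder(
            [VariantLocus("chr1", 100, "G", "T")], SUBCLONES + ["E"], {}
        )
        with pytest.raises(ValueError, match="lacks subclones"):
            call_method1([], table, quartet_tree)


class TestInferSets:
    def test_planted_segment_tallies(self, counts_builder):
        loci = [VariantLocus("chr1", 100 + i, "G", "T") for i in range(20)]
        cells = {}
        for i in range(20):
            for s in ("A", "B"):
                cells[(i, s)] = (15, 15)
        table = counts_builder(loci, SUBCLONES, cells)
        cands = [CoincidentGroup(l, frozenset({"A", "B"})) for l in loci]
        result = infer_sets(cands, table)
        assert result.counts == {frozenset({"A", "B"}): 20}

    def test_nested_sets_both_counted(self, counts_builder):
        subclones = ["A", "B", "C", "D", "E"]
        loci = [VariantLocus("chr1", 100 + i, "G", "T") for i in range(10)]
        cells = {}
        for i in range(5):
            for s in ("A", "B"):
                cells[(i, s)] = (15, 15)
        for i in range(5, 10):
            for s in ("A", "B", "C", "D"):
                cells[(i, s)] = (15, 15)
        table = counts_builder(loci, subclones, cells)
        cands = [
            CoincidentGroup(l, frozenset({"A", "B"})) for l in loci[:5]
        ] + [
            CoincidentGroup(l, frozenset({"A", "B", "C", "D"})) for l in loci[5:]
        ]
        result = infer_sets(cands, table)
        assert result.counts[frozenset({"A", "B"})] == 5
        assert result.counts[frozenset({"A", "B", "C", "D"})] == 5


class TestBuildTree:
    def test_laminar_family_to_tree(self):
        table = CladeFrequencyTable()
        for clade, n in [
            ({"A", "B"}, 350),
            ({"A", "B", "C"}, 200),
            ({"D", "E"}, 180),
            ({"A", "C"}, 2),
        ]:
            for _ in range(n):
                table.add(frozenset(clade))
        tree = build_tree_from_sets(table, ["A", "B", "C", "D", "E"])
        assert tree.topology() == frozenset(
            {
                frozenset({"A", "B"}),
                frozenset({"A", "B", "C"}),
                frozenset({"D", "E"}),
            }
        )
        assert not tree.generations_exact

    def test_gap_cutoff(self):
        table = CladeFrequencyTable()
        for clade, n in [({"A", "B"}, 350), ({"A", "C"}, 2)]:
            for _ in range(n):
                table.add(frozenset(clade))
        assert gap_min_count(table) == 350

    def test_non_laminar_error(self):
        table = CladeFrequencyTable()
        for clade in ({"A", "B"}, {"B", "C"}):
            for _ in range(100):
                table.add(frozenset(clade))
        with pytest.raises(ValueError, match="not laminar"):
            build_tree_from_sets(table, ["A", "B", "C"], min_count=50)

    def test_empty_table_error(self):
        with pytest.raises(ValueError, match="insufficient signal"):
            build_tree_from_sets(CladeFrequencyTable(), ["A", "B"])


class TestDendrogram:
    def _candidates(self, sets):
        return [
            CoincidentGroup(
                VariantLocus("chr1", 100 + i, "G", "T"), frozenset(s)
            )
            for i, s in enumerate(sets)
        ]

    def test_full_sharing_distance_zero(self):
        cands = self._candidates([{"A", "B"}] * 4)
        d = pairwise_dendrogram(cands, ["A", "B"])
        assert d.distances[0, 1] == 0.0

    def test_no_sharing_distance_one(self):
        cands = self._candidates([{"A", "C"}, {"B", "D"}])
        d = pairwise_dendrogram(cands, ["A", "B", "C", "D"])
        assert d.distances[0, 1] == 1.0

    def test_zero_hq_snvs_error(self):
        with pytest.raises(ValueError, match="no high-quality"):
            pairwise_dendrogram([], ["A", "B"])


class TestOrientation:
    def _first_division(self, quartet_tree, counts_builder):
        from lineageseq import BranchVariant

        table = het_table(counts_builder, ["A", "B"])
        grp = CoincidentGroup(table.loci[0], frozenset({"A", "B"}), quality=1.0)
        return BranchVariant(grp, "A,B")

    def test_outgroup_hom_ref_orients(self, quartet_tree, counts_builder):
        bv = self._first_division(quartet_tree, counts_builder)
        out = {("chr1", 100): AlleleCounts(30, 0)}
        rep = orient_root_split([bv], quartet_tree, outgroup_counts=out)
        assert rep.fraction_hom_to_het == 1.0
        assert rep.oriented[0][1] == frozenset({"A", "B"})

    def test_outgroup_missing_coverage_flags(self, quartet_tree, counts_builder):
        bv = self._first_division(quartet_tree, counts_builder)
        out = {("chr1", 100): AlleleCounts(0, 0)}
        rep = orient_root_split([bv], quartet_tree, outgroup_counts=out)
        assert rep.oriented == [] and len(rep.unoriented) == 1

    def test_no_reference_available(self, quartet_tree, counts_builder):
        bv = self._first_division(quartet_tree, counts_builder)
        rep = orient_root_split([bv], quartet_tree)
        assert rep.fraction_hom_to_het is None and len(rep.unoriented) == 1


def test_method1_method2_agree_on_simulated_lineage():
    """Tree-supplied and tree-inferred calling agree on >= 97% of branch
    calls in the simulator's standard regime."""
    from lineageseq import SimConfig, simulate_lineage

    cfg = SimConfig(
        rate_per_division=15, seed=7, chrom_lengths=(("chr1", 10_000_000),)
    )
    res = simulate_lineage(cfg)
    grouping = group_coincident(res.raw_snvs, res.counts.n_subclones)
    m1 = call_method1(
        grouping.candidates, res.counts, res.truth.tree,
        leaf_snvs=grouping.leaf_snvs,
    )
    sets = infer_sets(grouping.candidates, res.counts)
    tree2 = build_tree_from_sets(sets, res.counts.subclones, min_count=3)
    m2 = call_method1(
        grouping.candidates, res.counts, tree2, leaf_snvs=grouping.leaf_snvs
    )
    calls1 = {(bv.variant_locus, bv.clade) for bv in m1.branch}
    calls2 = {(bv.variant_locus, bv.clade) for bv in m2.branch}
    overlap = len(calls1 & calls2) / max(len(calls1 | calls2), 1)
    assert overlap >= 0.97
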