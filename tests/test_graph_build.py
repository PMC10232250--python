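"""Graph construction from reference + variants."""

import pytest

from edsmap import (
    EDSGraph, RefIndicator, build_eds, build_graph, classify_variants,
)
from edsmap.graph_build import (
    CNV, LARGE_DELETION, LARGE_INSERTION, SMALL, SNP, VariantRecord,
)
from conftest import TOY_GSTRING, TOY_INDICATOR, TOY_REF, TOY_VCF_ROWS


class TestClassify:
    def test_snp(self):
        kept, skipped = classify_variants([("c", 5, "A", ("G",), {})])
        assert kept[0].cls == SNP and not skipped

    def test_inversion_skipped(self):
        kept, skipped = classify_variants(
            [("c", 5, "A", ("<INV>",), {"SVTYPE": "INV", "END": 100})])
        assert not kept and skipped["unsupported_svtype"] == 1

    def test_mobile_element_insertion_skipped(self):
        kept, skipped = classify_variants(
            [("c", 5, "A", ("<INS:ME:ALU>",), {"SVTYPE": "INS"})])
        assert not kept and skipped["unsupported_svtype"] == 1

    def test_50bp_deletion_is_structural(self):
        ref = "A" + "CGT" * 17  # 52 bp, alt keeps the first base
        kept, _ = classify_variants([("c", 10, ref, (ref[0],), {})])
        assert kept[0].cls == LARGE_DELETION
        assert kept[0].ref_span == (10, 10 + len(ref) - 1)

    def test_19bp_indel_stays_small(self):
        ref = "A" * 20  # difference of 19 < the structural threshold
        kept, _ = classify_variants([("c", 10, ref, ("A",), {})])
        assert kept[0].cls == SMALL

    def test_large_insertion(self):
        kept, _ = classify_variants([("c", 3, "G", ("G" + "AT" * 15,), {})])
        assert kept[0].cls == LARGE_INSERTION

    def test_cnv_with_bounds(self):
        kept, _ = classify_variants(
            [("c", 2, "T", ("<CN3>",), {"SVTYPE": "CNV", "END": 9, "CN": 3})])
        assert kept[0].cls == CNV and kept[0].cn_bounds == (3, 3)

    def test_malformed_record_never_aborts(self):
        kept, skipped = classify_variants(
            [("c", "notanumber", "A", ("G",), {}),
             ("c", 5, "A", ("G",), {})])
        assert len(kept) == 1 and skipped["malformed"] == 1


class TestBuildEds:
    def test_no_variants_is_identity(self):
        text, flags, dropped = build_eds("ACGTACGT", [])
        assert text == "ACGTACGT" and flags == [1] * 8 and dropped == 0

    def test_running_example_fragment(self):
        smalls = [
            VariantRecord("toy", 4, "GA", ("G",), SMALL),
            VariantRecord("toy", 8, "AT", ("TA",), SMALL),
        ]
        text, flags, dropped = build_eds("NGACAATGA", smalls, offset=3)
        assert text == "NG(A|)CA(AT|TA)GA"
        assert dropped == 0
        ref_chars = [c for c, f in zip(text, flags) if f]
        assert "".join(ref_chars) == "NGACAATGA"

    def test_snp_symbol_and_multiallelic(self):
        text, _, _ = build_eds("TAT", [
            VariantRecord("c", 2, "A", ("G", "C"), SNP)])
        assert text == "T(A|G|C)T"

    def test_overlap_dropped_left_to_right(self):
        # a 2-bp replacement followed by an overlapping SNP: keep the first
        text, _, dropped = build_eds("TACG", [
            VariantRecord("c", 2, "AC", ("CA",), SMALL),
            VariantRecord("c", 3, "C", ("G",), SNP)])
        assert text == "T(AC|CA)G" and dropped == 1

    def test_ref_mismatch_skipped(self):
        text, _, dropped = build_eds("TTTT", [
            VariantRecord("c", 2, "A", ("G",), SNP)])
        assert text == "TTTT" and dropped == 1


class TestBuildGraph:
    def test_running_example(self, toy_built):
        graph, indicator = toy_built
        assert graph.gstring == TOY_GSTRING
        assert len(graph.gstring) == 22
        assert graph.fwd_edges == {1: frozenset({1}), 2: frozenset({1, 2})}
        assert graph.bwd_edges == {1: frozenset({1, 2}), 2: frozenset({2})}
        assert indicator.to_01_string() == TOY_INDICATOR
        assert indicator.total_ones() == len(TOY_REF)

    def test_successors_after_separator(self, toy_built):
        graph, _ = toy_built
        assert graph.successors_after_separator(2) == (4, 22)
        assert graph.successors_after_separator(1) == (4,)
        with pytest.raises(KeyError):
            graph.successors_after_separator(3)

    def test_three_node_chain_middle_separator(self):
        g = EDSGraph.from_gstring("AAA#CCC#GGG", edges=[(1, 1), (2, 2)])
        assert g.successors_after_separator(2) == (9,)
        assert g.predecessors_before_separator(2) == (7,)

    def test_no_structural_variants_single_node(self):
        variants, _ = classify_variants([("c", 2, "A", ("G",), {})])
        graph, bits, _ = build_graph({"c": "TACG"}, variants)
        assert "#" not in graph.gstring
        assert graph.fwd_edges == {} and graph.bwd_edges == {}
        assert len(graph.nodes) == 1

    def test_labels_rejoin_to_gstring(self, toy_built):
        graph, _ = toy_built
        assert "#".join(n.label for n in graph.nodes) == graph.gstring

    def test_large_deletion_bypass_edge(self):
        deleted = "G" * 30
        variants, _ = classify_variants(
            [("c", 4, "T" + deleted, ("T",), {})])
        graph, bits, _ = build_graph({"c": "ACGT" + deleted + "ACGT"}, variants)
        # nodes: ACGT | GGGG...G | ACGT with a bypass edge 1 -> 2
        assert [n.label for n in graph.nodes] == ["ACGT", deleted, "ACGT"]
        assert graph.fwd_edges == {1: frozenset({1, 2}), 2: frozenset({2})}
        assert RefIndicator(bits).total_ones() == 8 + 30

    def test_large_insertion_optional_node(self):
        ins = "TGCA" * 8
        variants, _ = classify_variants([("c", 4, "T", ("T" + ins,), {})])
        graph, bits, _ = build_graph({"c": "ACGTACGT"}, variants)
        assert [n.label for n in graph.nodes] == ["ACGT", ins, "ACGT"]
        assert graph.nodes[1].is_insertion
        assert graph.fwd_edges == {1: frozenset({1, 2}), 2: frozenset({2})}
        # inserted bases are not reference-origin
        assert RefIndicator(bits).total_ones() == 8

    def test_small_variant_at_sv_boundary_dropped(self):
        rows = list(TOY_VCF_ROWS) + [("toy", 2, "TN", ("T",), {})]
        variants, _ = classify_variants(rows)
        graph, _, dropped = build_graph({"toy": TOY_REF}, variants)
        assert graph.gstring == TOY_GSTRING
        assert dropped["small_at_sv_boundary"] == 1

    def test_overlapping_sv_skipped(self):
        rows = [
            ("toy", 2, "T", ("<DUP>",), {"SVTYPE": "DUP", "END": 11}),
            ("toy", 5, "A", ("<DUP>",), {"SVTYPE": "DUP", "END": 12}),
        ]
        variants, _ = classify_variants(rows)
        graph, _, dropped = build_graph({"toy": TOY_REF}, variants)
        assert dropped["sv_overlap"] == 1
        assert len(graph.nodes) == 3

    def test_multiple_chromosomes_are_independent(self):
        variants, _ = classify_variants(
            [("b", 2, "C", ("<DUP>",), {"SVTYPE": "DUP", "END": 6})])
        graph, bits, _ = build_graph(
            {"a": "ACGTT", "b": "CCGGTTAA"}, variants)
        # chromosome boundary '#' carries no jump edges
        names = [c.name for c in graph.chromosomes]
        assert names == ["a", "b"]
        sep_between = 1  # separator after chromosome a's single node
        assert sep_between not in graph.fwd_edges or \
            graph.fwd_edges[sep_between] == frozenset()
        assert RefIndicator(bits).total_ones() == 5 + 8
        assert graph.chromosomes[1].ones_before == 5
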