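"""Seeding, colinear chaining and the EDS-adapted alignment DP."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from edsmap import (
    EDSGraph, MappingParams, SeedPair, align_backward, align_forward,
    build_index, chain_scores, collect_pairs, map_read, read_minimizers,
    revcomp,
)
from helpers import (
    ToyGraph, naive_text_minimizers, pinned_forward_oracle,
    quadratic_chain_scores, random_graph_text,
)
from edsmap.minimizer_index import kmer_hash

READ = "TTAGAATCGA"


@pytest.fixture
def toy_index(toy_graph):
    return build_index(toy_graph, k=3, w=4, hash_mode="lex")


class TestReadMinimizers:
    def test_running_example(self):
        got = read_minimizers(READ, k=3, w=4)
        # AGA@3, AAT@5, ATC@6 as in the worked example; CGA starts at
        # r[8..10] (the last 3-mer of the 10 bp read)
        assert got == [("AGA", 3), ("AAT", 5), ("ATC", 6), ("CGA", 8)]

    def test_short_read_empty(self):
        assert read_minimizers("AC", k=3, w=4) == []

    def test_homopolymer(self):
        got = read_minimizers("AAAAAA", k=3, w=2)
        assert [i for _, i in got] == sorted(i for _, i in got)
        assert all(km == "AAA" for km, _ in got)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50)
    def test_equals_naive_scan(self, seed):
        rng = random.Random(seed)
        n = rng.randint(3, 50)
        read = "".join(rng.choice("ACGT") for _ in range(n))
        k = rng.randint(1, min(6, n))
        w = rng.randint(1, 6)
        got = {(i, km) for km, i in read_minimizers(read, k, w)}
        assert got == set(naive_text_minimizers(read, k, w, kmer_hash))


class TestPairsAndChaining:
    def test_running_example_pairs(self, toy_index):
        pairs = collect_pairs(read_minimizers(READ, 3, 4), toy_index)
        assert [(p.i, p.j) for p in pairs] == [(3, 4), (5, 11), (3, 17)]

    def test_no_hits(self, toy_index):
        assert collect_pairs([("GGG", 1)], toy_index) == []

    def test_shared_posting_position(self):
        idx_pairs = collect_pairs([("AAA", 2), ("AAT", 4)],
                                  _tiny_index({"AAA": (7,), "AAT": (7,)}))
        assert [(p.i, p.j) for p in idx_pairs] == [(2, 7), (4, 7)]

    def test_running_example_scores(self, toy_index):
        pairs = collect_pairs(read_minimizers(READ, 3, 4), toy_index)
        chain_scores(pairs, lam=2 * len(READ))
        scores = {(p.i, p.j): p.score for p in pairs}
        assert scores == {(3, 4): 1, (5, 11): 2, (3, 17): 1}

    def test_single_pair(self):
        pairs = [SeedPair(3, 10)]
        chain_scores(pairs, lam=100)
        assert pairs[0].score == 1

    def test_lambda_window_limits_chains(self):
        pairs = [SeedPair(1, 10), SeedPair(2, 1000)]
        chain_scores(pairs, lam=100)
        assert [p.score for p in pairs] == [1, 1]
        chain_scores(pairs, lam=10_000)
        assert [p.score for p in pairs] == [1, 2]

    @given(st.integers(0, 10_000))
    @settings(max_examples=60)
    def test_agrees_with_quadratic_oracle(self, seed):
        rng = random.Random(seed)
        m = rng.randint(1, 50)
        pairs = sorted(
            ((rng.randint(1, 30), rng.randint(1, 60)) for _ in range(m)),
            key=lambda t: (t[1], t[0]))
        lam = rng.choice([5, 20, 10**6])
        sp = [SeedPair(i=i, j=j) for i, j in pairs]
        chain_scores(sp, lam)
        assert [p.score for p in sp] == quadratic_chain_scores(sp, lam)

    def test_scores_stable_under_equal_j_permutations(self):
        pairs = [(1, 5), (4, 5), (2, 5), (3, 9)]
        base = None
        for perm in ([0, 1, 2, 3], [2, 0, 1, 3], [1, 2, 0, 3]):
            sp = [SeedPair(*pairs[t]) for t in perm]
            sp.sort(key=lambda p: (p.j, p.i))
            chain_scores(sp, lam=100)
            scores = {(p.i, p.j): p.score for p in sp}
            base = base or scores
            assert scores == base


def _tiny_index(postings):
    from edsmap.minimizer_index import MinimizerIndex
    return MinimizerIndex(k=3, w=4, trim_threshold=512, hash_mode="lex",
                          postings=postings)


class TestAlignForward:
    def test_worked_dp_table(self, toy_graph):
        trace = []
        res = align_forward(READ, toy_graph, 5, 11, 3, trace=trace)
        assert res.distance == 1
        assert res.gpos == 20  # optimal alignment detected in column 20
        by_col = dict(trace)
        assert by_col[14] == 3  # first complete alignment, 3 errors
        assert by_col[20] == 1

    def test_exact_substring_distance_zero(self):
        g = EDSGraph.from_gstring("ACGTACGTAC")
        res = align_forward("GTAC", g, 1, 3, 2)
        assert res.distance == 0 and res.gpos == 6
        assert res.ops == ("M",) * 4

    def test_bound_exceeded_returns_none(self):
        g = EDSGraph.from_gstring("AAAAAAA")
        assert align_forward("TTTT", g, 1, 2, 2) is None

    def test_seed_on_syntax_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            align_forward(READ, toy_graph, 5, 6, 3)

    def test_seed_inside_alternative(self, toy_graph):
        # seed on the A inside (A|): remaining alternatives are skipped
        res = align_forward("ACAAT", toy_graph, 1, 7, 1)
        assert res.distance == 0

    @given(st.integers(0, 10_000))
    @settings(max_examples=75)
    def test_agrees_with_enumeration_oracle(self, seed):
        """DP distance == min over enumerated path strings (via edlib)."""
        rng = random.Random(seed)
        gstring, edges = random_graph_text(rng, allow_n=False)
        graph = EDSGraph.from_gstring(gstring, edges)
        bases = [p for p, c in enumerate(gstring, 1) if c in "ACGT"]
        if not bases:
            return
        toy = ToyGraph(gstring, edges)
        for _ in range(4):
            j_star = rng.choice(bases)
            m = rng.randint(1, 8)
            read = "".join(rng.choice("ACGT") for _ in range(m))
            d = rng.randint(0, 3)
            res = align_forward(read, graph, 1, j_star, d)
            expect = pinned_forward_oracle(read, toy, j_star, d)
            got = res.distance if res is not None else None
            assert got == expect, (gstring, edges, read, j_star, d)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40)
    def test_pruning_never_changes_the_optimum(self, seed):
        rng = random.Random(seed)
        gstring, edges = random_graph_text(rng)
        graph = EDSGraph.from_gstring(gstring, edges)
        bases = [p for p, c in enumerate(gstring, 1) if c in "ACGTN"]
        if not bases:
            return
        for _ in range(3):
            j_star = rng.choice(bases)
            read = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            a = align_forward(read, graph, 1, j_star, 3, prune=True)
            b = align_forward(read, graph, 1, j_star, 3, prune=False)
            assert (a is None) == (b is None)
            if a is not None:
                assert a.distance == b.distance


class TestAlignBackward:
    def test_empty_prefix(self, toy_graph):
        res = align_backward(READ, toy_graph, 1, 4, 3)
        assert res.distance == 0 and res.ops == ()

    def test_running_example_spans_separator(self, toy_graph):
        # r[1..4] = TTAG aligned backward from the seed: the walk crosses
        # '#' into the first node; the G^ segment TT·NG? carries one extra
        # reference base (the C before the seed), one deletion
        res = align_backward(READ, toy_graph, 5, 11, 2)
        assert res.distance == 1
        assert res.gpos == 1  # alignment starts at the very first T

    def test_variant_free_backward_equals_reversal_oracle(self):
        import edlib
        text = "ACGTTGCA"
        g = EDSGraph.from_gstring(text)
        # prefix CGTT ending just before position 7: the reversal oracle is
        # the reversed prefix aligned to a prefix of the reversed upstream
        bwd = align_backward("CGTTA", g, 5, 7, 2)
        expect = edlib.align("CGTT"[::-1], text[:6][::-1],
                             mode="SHW")["editDistance"]
        assert bwd.distance == expect == 1
        assert bwd.gpos == 2  # alignment starts at the C

    def test_insertion_only_prefix(self):
        g = EDSGraph.from_gstring("ACGT")
        # prefix cannot extend left of position 1: chars become insertions
        res = align_backward("TTA", g, 3, 1, 2)
        assert res.distance == 2 and res.gpos == 1


class TestMapRead:
    def test_running_example_total(self, toy_graph, toy_index):
        res = map_read(READ, toy_graph, toy_index,
                       MappingParams(k=3, w=4, d=3))
        assert res is not None
        assert res.seed == (5, 11)
        assert res.distance == 2  # forward 1 + backward 1
        assert res.g_start == 1 and res.g_end == 20
        assert res.strand == "+"

    def test_exact_read_maps_with_distance_zero(self):
        g = EDSGraph.from_gstring("ACGTACGTTGACCA")
        idx = build_index(g, k=4, w=2)
        res = map_read("TACGTTGA", g, idx, MappingParams(k=4, w=2, d=1))
        assert res.distance == 0 and res.g_start == 4

    def test_reverse_complement_maps(self):
        g = EDSGraph.from_gstring("ACGTACGTTGACCA")
        idx = build_index(g, k=4, w=2)
        res = map_read(revcomp("TACGTTGA"), g, idx,
                       MappingParams(k=4, w=2, d=1))
        assert res.strand == "-" and res.g_start == 4

    def test_unmapped_is_none(self, toy_graph, toy_index):
        assert map_read("GGGGGGGGGG", toy_graph, toy_index,
                        MappingParams(k=3, w=4, d=1)) is None

    def test_read_spanning_self_loop(self, toy_graph, toy_index):
        # ATG·A (end of loop 1) then AGACA (start of loop 2, N read as A):
        # exercises the jump edge 2->1
        read = "ATGAAGACA"
        res = map_read(read, toy_graph, toy_index,
                       MappingParams(k=3, w=4, d=1))
        assert res is not None and res.distance == 0
        assert res.g_start == 13

    def test_termination_on_tiny_self_loop(self):
        g = EDSGraph.from_gstring("AC#G#TT", edges=[
            (1, 1), (2, 1), (2, 2)])
        idx = build_index(g, k=2, w=1)
        res = map_read("ACGGGTT", g, idx, MappingParams(k=2, w=1, d=2))
        assert res is not None and res.distance == 0

    def test_cigar_consumes_whole_read(self, toy_graph, toy_index):
        res = map_read(READ, toy_graph, toy_index,
                       MappingParams(k=3, w=4, d=3))
        consumed = 0
        import re
        for n, op in re.findall(r"(\d+)([MID])", res.cigar):
            if op in "MI":
                consumed += int(n)
        assert consumed == len(READ)
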