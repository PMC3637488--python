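"""Tree editing primitives and the three-directional lazy cache: break/join
topology contracts, memoization behavior, lazy-vs-from-scratch score
equality, and the O(|V|) rescoring guarantees."""

import numpy as np
import pytest

from gtapsearch.io_formats import read_newick
from gtapsearch.rag_align import CostModel, PRESET_COST_MODELS, RAG, counters
from gtapsearch.tree_core import UnrootedTree, join_score, join_trees

from conftest import (fresh_copy, random_bound_tree, random_topology,
                      scratch_rooted_length)

CM = CostModel(1, 1, 0)


def quartet(**seqs):
    t = read_newick("((a,b),(c,d));", {"a", "b", "c", "d"})
    if seqs:
        t.bind_sequences({k: RAG.from_sequence(v) for k, v in seqs.items()},
                         CM)
    return t


class TestBreakJoin:
    def test_break_internal_edge_partitions_cherries(self):
        t = quartet()
        (e,) = [e for e in t.edges() if all(not t.is_leaf(v) for v in e)]
        t1, t2 = t.break_edge(e)
        assert {t1.leaf_labels, t2.leaf_labels} == \
            {frozenset("ab"), frozenset("cd")}
        assert t1.n_edges() == t2.n_edges() == 1

    def test_break_leaf_edge_gives_singleton_and_triplet(self):
        t = quartet()
        t1, t2 = t.break_edge(t.leaf_edge("a"))
        single = t1 if t1.n_leaves == 1 else t2
        triple = t2 if t1.n_leaves == 1 else t1
        assert single.leaf_labels == frozenset("a")
        assert single.n_edges() == 0
        assert triple.leaf_labels == frozenset("bcd")
        assert triple.n_edges() == 3

    def test_break_edge_counts_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            t = random_topology([f"x{i}" for i in range(n)], rng)
            for e in t.edges():
                t1, t2 = t.break_edge(e)
                for comp in (t1, t2):
                    k = comp.n_leaves
                    assert comp.n_edges() == (0 if k == 1 else 2 * k - 3)

    def test_join_singleton_to_triplet(self):
        t = read_newick("(b,c,d);", {"b", "c", "d"})
        leaf = UnrootedTree.from_leaf("a")
        e = t.leaf_edge("b")
        joined = join_trees(t, leaf, e, None)
        assert joined.n_leaves == 4 and joined.n_edges() == 5

    def test_join_two_cherries(self):
        ab = join_trees(UnrootedTree.from_leaf("a"),
                        UnrootedTree.from_leaf("b"), None, None)
        cd = join_trees(UnrootedTree.from_leaf("c"),
                        UnrootedTree.from_leaf("d"), None, None)
        joined = join_trees(ab, cd, ab.edges()[0], cd.edges()[0])
        assert joined.is_isomorphic(read_newick("((a,b),(c,d));"))

    def test_join_rejects_shared_leaves(self):
        with pytest.raises(ValueError, match="share"):
            join_trees(UnrootedTree.from_leaf("a"),
                       UnrootedTree.from_leaf("a"), None, None)

    def test_break_then_rejoin_restores_topology(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 11))
            t = random_topology([f"x{i}" for i in range(n)], rng)
            e = t.edges()[int(rng.integers(t.n_edges()))]
            u, v = sorted(e)
            t1, t2 = t.break_edge(e)
            f1 = t.attachment_edge_after_break(e, u)
            f2 = t.attachment_edge_after_break(e, v)
            back = join_trees(t1, t2, f1, f2)
            assert back.is_isomorphic(t)


class TestDirectionalCache:
    def test_cherry_parent_assignments(self):
        t = quartet(a="A", b="A", c="C", d="C")
        va = t.vertex_of("a")
        (p,) = t.neighbors(va)
        other = [w for w in t.neighbors(p) if w not in
                 (va, t.vertex_of("b"))][0]
        # assignment of the cherry parent away from the internal edge is the
        # median of leaves a and b
        assert t.assignment(p, other) == RAG.from_sequence("A")

    def test_mixed_cherry_median(self):
        t = quartet(a="A", b="C", c="C", d="C")
        va = t.vertex_of("a")
        (p,) = t.neighbors(va)
        other = [w for w in t.neighbors(p)
                 if w not in (va, t.vertex_of("b"))][0]
        assert t.assignment(p, other).dump() == "AC"

    def test_assignment_is_memoized(self):
        t = quartet(a="ACGT", b="ACCT", c="TTTT", d="TTGT")
        v = t.internal_vertices()[0]
        u = [w for w in t.neighbors(v) if not t.is_leaf(w)][0]
        counters.reset()
        first = t.assignment(v, u)
        medians_after_first = counters.medians
        second = t.assignment(v, u)
        assert first is second
        assert counters.medians == medians_after_first == 1

    def test_identical_leaves_score_zero_everywhere(self):
        t = quartet(a="ACGT", b="ACGT", c="ACGT", d="ACGT")
        assert all(t.rooted_length(e) == 0 for e in t.edges())

    def test_triplet_single_mismatch(self):
        t = read_newick("(a,b,c);", {"a", "b", "c"})
        t.bind_sequences({"a": RAG.from_sequence("A"),
                          "b": RAG.from_sequence("A"),
                          "c": RAG.from_sequence("C")}, CM)
        assert all(t.rooted_length(e) == 1 for e in t.edges())

    @pytest.mark.parametrize("preset", PRESET_COST_MODELS,
                             ids=lambda c: f"{c.substitution}-{c.indel}-{c.gap_opening}")
    def test_lazy_equals_from_scratch_at_every_edge(self, preset):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            t, rags = random_bound_tree(n, rng, preset, max_len=40)
            for e in t.edges():
                assert t.rooted_length(e) == \
                    scratch_rooted_length(t, e, preset, rags)

    def test_refresh_median_budget(self):
        rng = np.random.default_rng(23)
        for n in (4, 6, 8, 12):
            t, _ = random_bound_tree(n, rng, CM, max_len=15)
            counters.reset()
            t.refresh_full()
            assert counters.medians <= 3 * (n - 2) + (2 * n - 3)
            # afterwards everything is memoized
            counters.reset()
            for e in t.edges():
                t.rooted_length(e)
            assert counters.alignments == 0

    def test_refresh_values_equal_lazy_values(self):
        rng = np.random.default_rng(29)
        t, _ = random_bound_tree(7, rng, CM, max_len=20)
        lazy = {e: t.rooted_length(e) for e in t.edges()}
        t2 = fresh_copy(t)
        t2.refresh_full()
        assert {e: t2.rooted_length(e) for e in t2.edges()} == lazy


class TestIncrementalRescoring:
    def test_observation1_break_rescoring_is_linear(self):
        # after a refresh, scoring both components of every possible break
        # costs O(|V|) new alignments in total (2 per break here)
        rng = np.random.default_rng(31)
        n = 10
        t, _ = random_bound_tree(n, rng, CM, max_len=25)
        t.refresh_full()
        counters.reset()
        for e in t.edges():
            u, v = sorted(e)
            t1, t2 = t.break_edge(e)
            for comp, end in ((t1, u), (t2, v)):
                if comp.n_edges() == 0:
                    continue
                attach = t.attachment_edge_after_break(e, end)
                comp.rooted_length(attach)
        n_breaks = 2 * n - 3
        assert counters.alignments <= 2 * n_breaks

    def test_observation2_join_scoring_is_one_alignment_per_pair(self):
        rng = np.random.default_rng(37)
        t, _ = random_bound_tree(9, rng, CM, max_len=25)
        internal = [e for e in t.edges()
                    if all(not t.is_leaf(v) for v in e)]
        t1, t2 = t.break_edge(internal[0])
        t1.refresh_full()
        t2.refresh_full()
        counters.reset()
        pairs = [(e1, e2) for e1 in t1.edges() for e2 in t2.edges()]
        for e1, e2 in pairs:
            join_score(t1, t2, e1, e2)
        assert counters.alignments == len(pairs)
        assert len(pairs) <= (2 * t1.n_leaves - 3) * (2 * t2.n_leaves - 3)

    def test_join_score_equals_materialized_rooted_length(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            t, _ = random_bound_tree(int(rng.integers(5, 9)), rng, CM,
                                     max_len=20)
            e = t.edges()[int(rng.integers(t.n_edges()))]
            t1, t2 = t.break_edge(e)
            if t1.n_edges() == 0 or t2.n_edges() == 0:
                continue
            e1 = t1.edges()[int(rng.integers(t1.n_edges()))]
            e2 = t2.edges()[int(rng.integers(t2.n_edges()))]
            predicted = join_score(t1, t2, e1, e2)
            joined = join_trees(t1, t2, e1, e2)
            from gtapsearch.tree_build import _new_join_edge
            new_edge = _new_join_edge(joined, t1, t2)
            assert fresh_copy(joined).rooted_length(new_edge) == predicted

    def test_cache_survives_random_edit_sequences(self):
        # after arbitrary break/join chains, cached scores match a tree
        # rebuilt with no caches at every edge (no stale reads)
        rng = np.random.default_rng(43)
        for trial in range(25):
            t, _ = random_bound_tree(7, rng, CM, max_len=15)
            for _ in range(8):
                e = t.edges()[int(rng.integers(t.n_edges()))]
                t1, t2 = t.break_edge(e)
                f1 = (t1.edges()[int(rng.integers(t1.n_edges()))]
                      if t1.n_edges() else None)
                f2 = (t2.edges()[int(rng.integers(t2.n_edges()))]
                      if t2.n_edges() else None)
                t = join_trees(t1, t2, f1, f2)
                clean = fresh_copy(t)
                for edge in t.edges():
                    assert t.rooted_length(edge) == clean.rooted_length(edge)
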