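"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest

from gtapsearch.rag_align import (CostModel, PRESET_COST_MODELS, RAG, align,
                                  counters)
from gtapsearch.tree_core import UnrootedTree, join_trees

BASES = "ACGT"


@pytest.fixture(params=PRESET_COST_MODELS,
                ids=lambda cm: f"{cm.substitution}-{cm.indel}-{cm.gap_opening}")
def cost_model(request) -> CostModel:
    return request.param


@pytest.fixture(autouse=True)
def _reset_counters():
    counters.reset()
    yield


def random_seq(rng: np.random.Generator, lo: int = 0, hi: int = 12) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(BASES), n))


# ---------------------------------------------------------------------------
# oracle 1: Biopython global affine aligner on plain sequences
# ---------------------------------------------------------------------------

def biopython_affine_distance(s1: str, s2: str, cm: CostModel) -> int:
    from Bio import Align

    if not s1 or not s2:
        gap = len(s1) + len(s2)
        return 0 if gap == 0 else cm.gap_opening + gap * cm.indel
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0
    aligner.mismatch_score = -cm.substitution
    aligner.open_gap_score = -(cm.gap_opening + cm.indel)
    aligner.extend_gap_score = -cm.indel
    return int(-aligner.score(s1, s2))


# ---------------------------------------------------------------------------
# oracle 2: exhaustive enumeration of all gapped alignments (tiny inputs)
# ---------------------------------------------------------------------------

def exhaustive_affine_distance(s1: str, s2: str, cm: CostModel) -> int:
    """Brute-force minimum over all alignments, scoring gap runs as
    gap_opening + run_length * indel.  Exponential; lengths <= ~6 only."""

    best = [None]

    def rec(i: int, j: int, cost: int, state: int) -> None:
        # state: 0 none/match, 1 gap run in s2 (consuming s1), 2 gap in s1
        if best[0] is not None and cost >= best[0]:
            return
        if i == len(s1) and j == len(s2):
            best[0] = cost if best[0] is None else min(best[0], cost)
            return
        if i < len(s1) and j < len(s2):
            d = 0 if s1[i] == s2[j] else cm.substitution
            rec(i + 1, j + 1, cost + d, 0)
        if i < len(s1):
            opening = cm.gap_opening if state != 1 else 0
            rec(i + 1, j, cost + opening + cm.indel, 1)
        if j < len(s2):
            opening = cm.gap_opening if state != 2 else 0
            rec(i, j + 1, cost + opening + cm.indel, 2)

    rec(0, 0, 0, 0)
    return best[0]


# ---------------------------------------------------------------------------
# oracle 3: from-scratch single-rooted tree length (no caches)
# ---------------------------------------------------------------------------

def scratch_rooted_length(t: UnrootedTree, e, cm: CostModel,
                          rags: Dict[str, RAG]) -> int:
    """Independent post-order recomputation of the DO tree length rooted at
    the subdivision vertex of ``e``, using only adjacency and pairwise
    align() — none of the tree's caches.  Operands are ordered by the
    smallest leaf label on each side, the package's canonical convention."""

    def min_label(v: int, parent: int) -> str:
        if t.is_leaf(v):
            return t.label_of(v)
        return min(min_label(w, v) for w in t.neighbors(v) if w != parent)

    def down(v: int, parent: int) -> Tuple[RAG, int]:
        if t.is_leaf(v):
            return rags[t.label_of(v)], 0
        kids = sorted((w for w in t.neighbors(v) if w != parent),
                      key=lambda w: min_label(w, v))
        (r1, c1), (r2, c2) = down(kids[0], v), down(kids[1], v)
        res = align(r1, r2, cm)
        return res.median, c1 + c2 + res.cost

    u, v = sorted(e)
    if min_label(v, u) < min_label(u, v):
        u, v = v, u
    (ru, cu), (rv, cv) = down(u, v), down(v, u)
    return cu + cv + align(ru, rv, cm).cost


def fresh_copy(t: UnrootedTree) -> UnrootedTree:
    """Same topology and bindings, empty caches."""
    return UnrootedTree({v: list(t.neighbors(v)) for v in t.vertices()},
                        {v: t.label_of(v) for v in t.vertices()
                         if t.is_leaf(v)},
                        dict(t._leaf_rag), t.cost_model)


# ---------------------------------------------------------------------------
# oracle 4: exact tiny Steiner (TAP) optimum by enumerating assignments
# ---------------------------------------------------------------------------

def exact_tap_optimum(t: UnrootedTree, rags: Dict[str, str],
                      cm: CostModel, max_len: int) -> int:
    """Exact tree alignment optimum: minimize, over all assignments of plain
    sequences (length <= max_len) to internal vertices, the sum of exact
    affine edit distances along the edges.  Exponential; n <= 4 only."""
    alphabet: List[str] = [""]
    for L in range(1, max_len + 1):
        alphabet += ["".join(p) for p in itertools.product(BASES, repeat=L)]

    @lru_cache(maxsize=None)
    def edist(x: str, y: str) -> int:
        return exhaustive_affine_distance(x, y, cm)

    internals = t.internal_vertices()
    edges = [tuple(sorted(e)) for e in t.edges()]
    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        for v in t.vertices():
            if t.is_leaf(v):
                assign[v] = rags[t.label_of(v)]
        total = sum(edist(assign[a], assign[b]) for a, b in edges)
        if best is None or total < best:
            best = total
    return best


# ---------------------------------------------------------------------------
# random trees over random sequences
# ---------------------------------------------------------------------------

def random_topology(labels: List[str],
                    rng: np.random.Generator) -> UnrootedTree:
    """Uniform-ish random binary topology by random sequential joins."""
    trees = [UnrootedTree.from_leaf(lab) for lab in labels]
    while len(trees) > 1:
        i, j = sorted(rng.choice(len(trees), 2, replace=False))
        a, b = trees[i], trees[j]
        ea = a.edges()[int(rng.integers(a.n_edges()))] if a.n_edges() else None
        eb = b.edges()[int(rng.integers(b.n_edges()))] if b.n_edges() else None
        joined = join_trees(a, b, ea, eb)
        trees = [x for k, x in enumerate(trees) if k not in (i, j)]
        trees.append(joined)
    return trees[0]


def random_bound_tree(n: int, rng: np.random.Generator, cm: CostModel,
                      max_len: int = 20
                      ) -> Tuple[UnrootedTree, Dict[str, RAG]]:
    labels = [f"L{i}" for i in range(n)]
    rags = {lab: RAG.from_sequence(random_seq(rng, 0, max_len))
            for lab in labels}
    t = random_topology(labels, rng)
    t.bind_sequences(rags, cm)
    return t, rags


def all_topologies(labels: List[str]) -> List[UnrootedTree]:
    """Every unrooted binary topology on the labels, by stepwise addition."""
    from gtapsearch.io_formats import read_newick

    trees = [read_newick(f"({labels[0]},{labels[1]},{labels[2]});",
                         set(labels[:3]))]
    for lab in labels[3:]:
        trees = [join_trees(t, UnrootedTree.from_leaf(lab), e, None)
                 for t in trees for e in t.edges()]
    return list({t.splits(): t for t in trees}.values())


def optimum_recovery_rate(master_seed: int, n_leaves: int = 5,
                          n_instances: int = 8,
                          cm: Optional[CostModel] = None
                          ) -> Tuple[int, int]:
    """Greedy TBR started from every possible topology of random
    short-sequence instances: (starts that reached the exhaustive-enumeration
    global optimum, total starts).  Sequence lengths are drawn uniformly
    from 6..12 per instance; each start uses its own search seed."""
    from gtapsearch.local_search import SearchPolicy, local_search

    cm = cm or CostModel(1, 1, 0)
    labels = [f"L{i}" for i in range(n_leaves)]
    rng = np.random.default_rng(master_seed)
    total = hits = 0
    for _ in range(n_instances):
        length = int(rng.integers(6, 13))
        rags = {lab: RAG.from_sequence(
            "".join(rng.choice(list(BASES), length))) for lab in labels}
        topos = all_topologies(labels)
        lengths = []
        for t in topos:
            t.bind_sequences(rags, cm)
            lengths.append(min(t.rooted_length(e) for e in t.edges()))
        optimum = min(lengths)
        for t in topos:
            seed = int(rng.integers(2 ** 31))
            trace = local_search(fresh_copy(t), SearchPolicy(seed=seed))
            final = min(trace.final_tree.rooted_length(e)
                        for e in trace.final_tree.edges())
            total += 1
            hits += final == optimum
    return hits, total
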