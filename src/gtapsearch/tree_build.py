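"""Initial tree construction.

Wagner builds add leaves one at a time to the growing tree, trying every
join edge and keeping the best (or, with lookahead k, the k best) partial
trees.  The addition order is either a uniformly random permutation (RAS)
or derived from a BFS of the minimum spanning tree of the leaf-to-leaf DO
distances, perturbed between iterations by adjacent swaps (MST-Wagner).
Union pruning restricts candidate join edges to those whose vertex-block
union is at small DO distance from the incoming leaf.  Neighbor joining is
provided as a deterministic distance-based alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .rag_align import RAG, CostModel, distance
from .tap_scoring import ScoreBound, improve_on_join, score_ne
from .tree_core import UnrootedTree, join_score, join_trees
from . import union_index as ui

__all__ = ["AdditionSequence", "ras", "mst_addition", "wagner_build",
           "nj_build", "pairwise_distances"]

#: Default admission threshold for union-pruned joins.
UNION_THRESHOLD = 1.17


@dataclass(frozen=True)
class AdditionSequence:
    """A permutation of leaf labels plus the generator state that made it."""

    order: Tuple[str, ...]
    seed: Optional[int] = None
    iteration: int = 0

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("addition sequence must be a permutation")


def ras(leaves: Sequence[str], rng: np.random.Generator,
        seed: Optional[int] = None) -> AdditionSequence:
    """Random Addition Sequence: a uniform random permutation of the
    leaves; deterministic given the generator state."""
    order = [leaves[i] for i in rng.permutation(len(leaves))]
    return AdditionSequence(tuple(order), seed=seed)


def pairwise_distances(rags: Dict[str, RAG],
                       cost: CostModel) -> Tuple[List[str], np.ndarray]:
    """Leaf-to-leaf DO distance matrix (labels sorted lexicographically)."""
    labels = sorted(rags)
    n = len(labels)
    mat = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = distance(rags[labels[i]], rags[labels[j]], cost)
            mat[i, j] = mat[j, i] = d
    return labels, mat


def _mst_bfs_order(labels: List[str], mat: np.ndarray) -> List[str]:
    """Prim MST from the lexicographically smallest leaf (ties broken by
    label order), then BFS of the MST from the same start."""
    n = len(labels)
    order_idx = sorted(range(n), key=lambda i: labels[i])
    start = order_idx[0]
    in_tree = {start}
    mst_adj: Dict[int, List[int]] = {i: [] for i in range(n)}
    while len(in_tree) < n:
        best = None
        for i in sorted(in_tree, key=lambda i: labels[i]):
            for j in order_idx:
                if j in in_tree:
                    continue
                cand = (int(mat[i, j]), labels[i], labels[j], i, j)
                if best is None or cand < best:
                    best = cand
        _, _, _, i, j = best
        mst_adj[i].append(j)
        mst_adj[j].append(i)
        in_tree.add(j)
    # BFS with neighbor order by label
    seen = {start}
    queue = [start]
    order = []
    while queue:
        v = queue.pop(0)
        order.append(labels[v])
        for w in sorted(mst_adj[v], key=lambda w: labels[w]):
            if w not in seen:
                seen.add(w)
                queue.append(w)
    return order


def mst_addition(labels_or_rags, dist_matrix, rng: np.random.Generator,
                 iteration: int = 0) -> AdditionSequence:
    """MST-derived addition sequence.

    Q(0) is the BFS order of the leaf MST; Q(k) is obtained from Q(k-1) by a
    left-to-right pass swapping adjacent positions independently with
    probability 0.5.  ``rng`` draws the swap coins for iterations 1..k.
    """
    if isinstance(labels_or_rags, dict):
        labels = sorted(labels_or_rags)
    else:
        labels = list(labels_or_rags)
    order = _mst_bfs_order(labels, np.asarray(dist_matrix))
    for _ in range(iteration):
        for i in range(len(order) - 1):
            if rng.random() < 0.5:
                order[i], order[i + 1] = order[i + 1], order[i]
    return AdditionSequence(tuple(order), iteration=iteration)


def _admissible_edges(tree: UnrootedTree, index: "ui.UnionIndex",
                      leaf_rag: RAG, cost: CostModel,
                      threshold: float) -> List:
    """Join edges admitted by union pruning: block bound within
    ``threshold`` times the minimum block bound (the incoming leaf is a
    union of its own)."""
    bounds = {}
    for i, block in enumerate(index.blocks):
        bounds[i] = distance(block.union, leaf_rag, cost)
    lo = min(bounds.values())
    edges = []
    for e in tree.edges():
        b = min(bounds[index.vertex_block[v]] for v in e)
        if b <= threshold * lo:
            edges.append((b, sorted(e), e))
    edges.sort(key=lambda t: (t[0], t[1]))
    return [e for _, _, e in edges]


def wagner_build(rags: Dict[str, RAG], addition: AdditionSequence,
                 cost: CostModel, lookahead: int = 1,
                 union_prune: bool = False,
                 threshold: float = UNION_THRESHOLD,
                 mode: str = "ne",
                 stats: Optional[Dict[str, int]] = None) -> UnrootedTree:
    """Greedy Wagner construction with beam-width ``lookahead``.

    Starts from the unique topology on the first three leaves; each further
    leaf is tried at every edge (or only union-admissible edges) of each
    retained partial tree, scored at the new join edge (NE) or with the
    extra adjacent roots folded in (E); the ``lookahead`` best partial
    trees are retained.
    """
    order = list(addition.order)
    if set(order) != set(rags):
        raise ValueError("addition sequence does not match the leaf set")
    if len(order) < 3:
        raise ValueError("need at least 3 leaves")
    if mode not in ("e", "ne"):
        raise ValueError(f"mode must be 'e' or 'ne', got {mode!r}")

    def leaf_tree(lab: str) -> UnrootedTree:
        return UnrootedTree.from_leaf(lab, rags[lab], cost)

    two = join_trees(leaf_tree(order[0]), leaf_tree(order[1]), None, None)
    e0 = two.edges()[0]
    start = join_trees(two, leaf_tree(order[2]), e0, None)
    beam: List[Tuple[int, UnrootedTree, Optional[ui.UnionIndex]]] = [
        (0, start, None)]

    for lab in order[3:]:
        new_rag = rags[lab]
        candidates: List[Tuple[int, int, UnrootedTree]] = []
        counter = 0
        for _, tree, index in beam:
            if union_prune:
                if index is None:
                    index = ui.build_index(tree, cost)
                edges = _admissible_edges(tree, index, new_rag, cost,
                                          threshold)
            else:
                edges = tree.edges()
            leaf_t = leaf_tree(lab)
            for e in edges:
                ne_len = join_score(tree, leaf_t, e, None)
                if stats is not None:
                    stats["joins_evaluated"] = \
                        stats.get("joins_evaluated", 0) + 1
                candidates.append((ne_len, counter, tree, leaf_t, e))
                counter += 1
        candidates.sort(key=lambda c: (c[0], c[1]))
        kept = candidates[:max(lookahead, 1)]
        beam = []
        for ne_len, _, tree, leaf_t, e in kept:
            cand = join_trees(tree, leaf_t, e, None)
            new_edge = _new_join_edge(cand, tree, leaf_t)
            if mode == "e":
                bound = improve_on_join(None, cand, new_edge)
                length = bound.best_length
            else:
                length = score_ne(cand, new_edge).best_length
            beam.append((length, cand, None))
        beam.sort(key=lambda b: b[0])

    if stats is not None:
        stats["final_length"] = beam[0][0]
    return beam[0][1]


def _new_join_edge(joined: UnrootedTree, left: UnrootedTree,
                   right: UnrootedTree):
    """The edge created by the most recent join: connects the two new
    subdivision vertices (the vertices absent from both inputs), or reaches
    a single-vertex component directly."""
    old = set(left._adj) | set(right._adj)
    new_vs = [v for v in joined.vertices() if v not in old]
    if len(new_vs) == 2:
        return frozenset(new_vs)
    if len(new_vs) == 1:
        x = new_vs[0]
        single = left if left.n_edges() == 0 else right
        (v,) = single._adj
        return frozenset((x, v))
    # both components were single vertices
    return joined.edges()[0]


def nj_build(dist_matrix: np.ndarray, labels: Sequence[str],
             rags: Optional[Dict[str, RAG]] = None,
             cost: Optional[CostModel] = None) -> UnrootedTree:
    """Neighbor joining with deterministic tie-breaking (smallest Q value,
    then lexicographically smallest label pair); fully binary output,
    invariant under permutations of the input order."""
    mat = np.asarray(dist_matrix, dtype=float)
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be square and symmetric")
    if (mat < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    n = mat.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if len(labels) != n:
        raise ValueError("labels do not match matrix size")

    # canonicalize processing order so input permutation cannot matter
    perm = sorted(range(n), key=lambda i: labels[i])
    names = [labels[i] for i in perm]
    D = {(a, b): float(mat[i, j])
         for ai, (a, i) in enumerate(zip(names, perm))
         for b, j in zip(names, perm)}
    nodes = {nm: UnrootedTree.from_leaf(
        nm, rags[nm] if rags else None, cost) for nm in names}
    # each active item: (sort key, subtree, attach edge or None)
    active: Dict[str, Tuple[UnrootedTree, Optional[frozenset]]] = {
        nm: (nodes[nm], None) for nm in names}
    dist = {k: v for k, v in D.items() if k[0] != k[1]}

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(a, b)]

    items = list(names)
    while len(items) > 3:
        r = {a: sum(d(a, b) for b in items if b != a) for a in items}
        best = None
        for i, a in enumerate(items):
            for b in items[i + 1:]:
                q = (len(items) - 2) * d(a, b) - r[a] - r[b]
                key = (q, min(a, b), max(a, b))
                if best is None or key < best:
                    best = key
        _, a, b = best
        new_name = f"({a}+{b})"
        ta, ea = active.pop(a)
        tb, eb = active.pop(b)
        joined = join_trees(ta, tb, ea, eb)
        attach = _new_join_edge(joined, ta, tb)
        active[new_name] = (joined, attach)
        for c in items:
            if c in (a, b):
                continue
            nd = 0.5 * (d(a, c) + d(b, c) - d(a, b))
            dist[(new_name, c)] = dist[(c, new_name)] = nd
        items = [c for c in items if c not in (a, b)] + [new_name]

    a, b, c = sorted(items)
    ta, ea = active.pop(a)
    tb, eb = active.pop(b)
    tc, ec = active.pop(c)
    two = join_trees(ta, tb, ea, eb)
    mid = _new_join_edge(two, ta, tb)
    return join_trees(two, tc, mid, ec)
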