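"""Union index: disjoint connected vertex blocks carrying union RAGs.

Folding the RAG union over the DO assignments of a small connected block of
vertices yields a RAG that contains every member's assignment sequences.
The DO distance between two block unions therefore lower-bounds the best
member-pair distance (the quantity TBR joins try to minimize), so block
unions can rank and prune candidate join-edge pairs cheaply.  Block size is
fixed at 12 vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

from .rag_align import RAG, CostModel, distance, merge_union
from .tree_core import Edge, UnrootedTree

__all__ = ["BLOCK_SIZE", "UnionIndex", "build_index", "lower_bound",
           "update_after_accept"]

#: Maximum vertices per block (fixed experimentally in the original study).
BLOCK_SIZE = 12


@dataclass(frozen=True)
class Block:
    vertices: FrozenSet[int]
    union: RAG


@dataclass
class UnionIndex:
    """Partition of a tree's vertices into connected blocks of at most
    :data:`BLOCK_SIZE` members, each with the union RAG of its members'
    root-directed assignments."""

    blocks: List[Block]
    vertex_block: Dict[int, int]  # vertex -> index into blocks
    root_edge: Edge
    cost: CostModel
    # memo: member-assignment fingerprint -> union RAG (reused across updates)
    _union_memo: Dict[Tuple[int, ...], RAG] = field(default_factory=dict)

    def block_of(self, v: int) -> Block:
        return self.blocks[self.vertex_block[v]]

    def block_of_edge(self, e: Edge) -> List[Block]:
        return [self.blocks[self.vertex_block[v]] for v in sorted(e)]

    def dump(self) -> str:
        lines = []
        for i, b in enumerate(self.blocks):
            lines.append(f"block {i}: vertices={sorted(b.vertices)} "
                         f"union={b.union.dump()}")
        return "\n".join(lines)


def _root_directed_assignments(t: UnrootedTree,
                               root_edge: Edge) -> Tuple[Dict[int, RAG],
                                                         Dict[int, int],
                                                         List[int]]:
    """Per-vertex assignment induced by rooting at ``root_edge``'s
    subdivision vertex, plus parent pointers and a post-order listing."""
    u, v = sorted(root_edge)
    parent: Dict[int, Optional[int]] = {u: None, v: None}
    order = [u, v]
    for w in order:
        for x in t.neighbors(w):
            if x not in parent and not ({w, x} == set(root_edge)):
                parent[x] = w
                order.append(x)
    assign = {}
    for w in order:
        p = parent[w]
        if p is None:
            # child of the root subdivision vertex: direction away from the
            # other endpoint of the root edge
            other = v if w == u else u
            assign[w] = t.assignment(w, other)
        else:
            assign[w] = t.assignment(w, p)
    post = list(reversed(order))
    return assign, {w: p for w, p in parent.items() if p is not None}, post


def _partition(t: UnrootedTree, root_edge: Edge,
               parent: Dict[int, int]) -> List[List[int]]:
    """Greedy connected blocks of <= BLOCK_SIZE along the post-order of the
    rooted traversal: each vertex merges its children's still-open blocks
    while the size bound allows, closing the rest."""
    children: Dict[int, List[int]] = {w: [] for w in t.vertices()}
    roots = []
    for w in t.vertices():
        p = parent.get(w)
        if p is None:
            roots.append(w)
        else:
            children[p].append(w)
    closed: List[List[int]] = []

    def visit(w: int) -> List[int]:
        open_block = [w]
        for c in sorted(children[w]):
            cb = visit(c)
            if len(open_block) + len(cb) <= BLOCK_SIZE:
                open_block.extend(cb)
            else:
                closed.append(cb)
        return open_block

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * t.n_leaves + 100))
    try:
        opens = [visit(r) for r in sorted(roots)]
    finally:
        sys.setrecursionlimit(old)
    # the root edge connects the two sides, so their open blocks may merge
    merged = opens[0]
    for ob in opens[1:]:
        if len(merged) + len(ob) <= BLOCK_SIZE:
            merged.extend(ob)
        else:
            closed.append(ob)
    closed.append(merged)
    return closed


def _fold_union(members: List[int], assign: Dict[int, RAG],
                cost: CostModel, memo: Dict[Tuple[int, ...], RAG]) -> RAG:
    key = tuple(hash(assign[w]) for w in members)
    hit = memo.get(key)
    if hit is not None:
        return hit
    acc = assign[members[0]]  # union of a single RAG is itself
    for w in members[1:]:
        acc = merge_union(acc, assign[w], cost)
    memo[key] = acc
    return acc


def build_index(t: UnrootedTree, cost: Optional[CostModel] = None,
                root_edge: Optional[Edge] = None,
                _memo: Optional[Dict] = None) -> UnionIndex:
    """Build the union index of ``t`` with assignments directed by rooting
    at ``root_edge`` (default: the edge at the lexicographically smallest
    leaf)."""
    cost = cost or t.cost_model
    if t.n_edges() == 0:
        # a lone leaf is a union of its own
        (v,) = t.vertices()
        return UnionIndex(
            blocks=[Block(frozenset((v,)), t._leaf_rag[v])],
            vertex_block={v: 0}, root_edge=None, cost=cost,
            _union_memo=_memo if _memo is not None else {})
    if root_edge is None:
        root_edge = t.leaf_edge(min(t.leaf_labels))
    assign, parent, _ = _root_directed_assignments(t, root_edge)
    memo = _memo if _memo is not None else {}
    blocks = []
    vertex_block = {}
    for members in _partition(t, root_edge, parent):
        members = sorted(members)
        union = _fold_union(members, assign, cost, memo)
        for w in members:
            vertex_block[w] = len(blocks)
        blocks.append(Block(frozenset(members), union))
    return UnionIndex(blocks=blocks, vertex_block=vertex_block,
                      root_edge=root_edge, cost=cost, _union_memo=memo)


def lower_bound(index_a: UnionIndex, block_x: Block,
                index_b: UnionIndex, block_y: Block,
                cost: Optional[CostModel] = None) -> int:
    """DO distance between two block unions: a heuristic lower bound on the
    best member-pair distance between the blocks."""
    cost = cost or index_a.cost
    return distance(block_x.union, block_y.union, cost)


def update_after_accept(index: UnionIndex, t: UnrootedTree,
                        best_root: Edge) -> UnionIndex:
    """Recompute the index for the just-accepted tree, directing assignments
    by its best subdivision vertex.  Block unions whose member assignments
    are unchanged are reused from the memo, so only blocks touched by the
    move trigger new union merges."""
    return build_index(t, index.cost, best_root, _memo=index._union_memo)
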