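"""Unrooted binary trees with break/join editing and the three-directional,
lazily memoized direct-optimization cache.

Every edge of an unrooted tree carries an implicit *subdivision vertex*, a
candidate root for DO scoring.  For each internal vertex we may need its DO
assignment in any of the three directions away from its incident edges, so
the cache keys directed edges ``(v, u)``: the entry holds the RAG assigned to
the subtree hanging from ``v`` on the side away from ``u`` together with that
subtree's accumulated alignment cost.  Entries are computed on demand and
memoized; break/join operations carry over exactly the entries whose
computation did not involve the edited edge, so rescoring after a tree edit
costs O(|V|) new alignments rather than a full recomputation.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

from . import rag_align
from .rag_align import RAG, CostModel, align

__all__ = ["UnrootedTree", "Edge", "break_edge", "join_trees", "join_score"]

Edge = FrozenSet[int]

# Vertex ids are process-global so that trees produced by independent builds
# can be joined without collisions; ids are stable across edits, letting
# memoized entries survive where still valid.
_vertex_ids = itertools.count(1)


def _edge(u: int, v: int) -> Edge:
    return frozenset((u, v))


class UnrootedTree:
    """Leaf-labeled unrooted binary tree (internal vertices of degree 3).

    Single leaves and two-leaf trees are permitted as degenerate cases (they
    arise from tree breaking); with ``n >= 3`` leaves the tree has exactly
    ``n - 2`` internal vertices and ``2n - 3`` edges.
    """

    def __init__(
        self,
        adj: Dict[int, List[int]],
        leaf_label: Dict[int, str],
        leaf_rag: Optional[Dict[int, RAG]] = None,
        cost: Optional[CostModel] = None,
    ):
        self._adj = adj
        self._leaf_label = leaf_label
        self._label_vertex = {lab: v for v, lab in leaf_label.items()}
        self._leaf_rag = leaf_rag or {}
        self.cost_model = cost
        # directed cache: (v, u) -> (RAG, accumulated subtree cost)
        self._dir: Dict[Tuple[int, int], Tuple[RAG, int]] = {}
        # smallest leaf label on v's side of edge (v, u); a per-tree memo
        # (trees are topologically immutable, edits build new objects)
        self._lbl: Dict[Tuple[int, int], str] = {}
        # edge cache: edge -> (subdivision RAG, subdivision alignment cost,
        #                      rooted tree length at the edge)
        self._edge: Dict[Edge, Tuple[RAG, int, int]] = {}
        self._validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_leaf(cls, label: str, rag: Optional[RAG] = None,
                  cost: Optional[CostModel] = None) -> "UnrootedTree":
        v = next(_vertex_ids)
        return cls({v: []}, {v: label},
                   {v: rag} if rag is not None else {}, cost)

    @classmethod
    def from_splits(cls, parent_children: Dict[str, Sequence],
                    cost: Optional[CostModel] = None) -> "UnrootedTree":
        raise NotImplementedError  # pragma: no cover - reserved

    def _validate(self) -> None:
        verts = set(self._adj)
        if not verts:
            raise ValueError("tree must have at least one vertex")
        for v, nbrs in self._adj.items():
            if len(nbrs) != len(set(nbrs)):
                raise ValueError("duplicate adjacency entry")
            for w in nbrs:
                if w not in verts or v not in self._adj[w]:
                    raise ValueError("adjacency is not symmetric")
        n_edges = sum(len(nb) for nb in self._adj.values()) // 2
        if n_edges != len(verts) - 1:
            raise ValueError("tree must be connected and acyclic")
        for v in verts:
            deg = len(self._adj[v])
            if v in self._leaf_label:
                if deg > 1:
                    raise ValueError(f"leaf {self._leaf_label[v]!r} has degree {deg}")
            elif deg != 3:
                raise ValueError(f"internal vertex {v} has degree {deg}, not 3")
        if len(self._label_vertex) != len(self._leaf_label):
            raise ValueError("duplicate leaf labels")

    # -- basic queries ----------------------------------------------------

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_label)

    @property
    def leaf_labels(self) -> FrozenSet[str]:
        return frozenset(self._label_vertex)

    def vertices(self) -> List[int]:
        return sorted(self._adj)

    def internal_vertices(self) -> List[int]:
        return sorted(v for v in self._adj if v not in self._leaf_label)

    def is_leaf(self, v: int) -> bool:
        return v in self._leaf_label

    def label_of(self, v: int) -> str:
        return self._leaf_label[v]

    def vertex_of(self, label: str) -> int:
        return self._label_vertex[label]

    def neighbors(self, v: int) -> List[int]:
        return list(self._adj[v])

    def edges(self) -> List[Edge]:
        out = []
        for v in sorted(self._adj):
            for w in self._adj[v]:
                if v < w:
                    out.append(_edge(v, w))
        return out

    def n_edges(self) -> int:
        return sum(len(nb) for nb in self._adj.values()) // 2

    def has_edge(self, e: Edge) -> bool:
        u, v = sorted(e)
        return u in self._adj and v in self._adj[u]

    def leaf_edge(self, label: str) -> Edge:
        """The edge incident to the given leaf."""
        v = self._label_vertex[label]
        (w,) = self._adj[v]
        return _edge(v, w)

    def bind_sequences(self, rags: Dict[str, RAG], cost: CostModel) -> None:
        """Attach leaf RAGs and a cost model; resets all caches."""
        missing = self.leaf_labels - set(rags)
        if missing:
            raise ValueError(f"missing sequences for leaves: {sorted(missing)}")
        self._leaf_rag = {self._label_vertex[lab]: rags[lab]
                          for lab in self.leaf_labels}
        self.cost_model = cost
        self._dir.clear()
        self._edge.clear()

    def _require_bound(self) -> CostModel:
        if self.cost_model is None or len(self._leaf_rag) < self.n_leaves:
            raise ValueError("tree has no bound sequences/cost model; "
                             "call bind_sequences() first")
        return self.cost_model

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree(
            {v: list(nb) for v, nb in self._adj.items()},
            dict(self._leaf_label), dict(self._leaf_rag), self.cost_model,
        )
        t._dir = dict(self._dir)
        t._edge = dict(self._edge)
        t._lbl = dict(self._lbl)
        return t

    # -- splits and canonical form ---------------------------------------

    def _component_labels(self, v: int, banned: int) -> FrozenSet[str]:
        """Leaf labels reachable from v without crossing edge (v, banned)."""
        seen = {v}
        stack = [v]
        labels = []
        while stack:
            w = stack.pop()
            if w in self._leaf_label:
                labels.append(self._leaf_label[w])
            for x in self._adj[w]:
                if x not in seen and not (w == v and x == banned):
                    seen.add(x)
                    stack.append(x)
        return frozenset(labels)

    def splits(self) -> FrozenSet[FrozenSet[str]]:
        """All bipartitions, each identified by the side not containing the
        lexicographically smallest leaf label."""
        if self.n_leaves < 2:
            return frozenset()
        smallest = min(self._label_vertex)
        out = set()
        for e in self.edges():
            u, v = sorted(e)
            side = self._component_labels(u, v)
            if smallest in side:
                side = self.leaf_labels - side
            out.add(side)
        return frozenset(out)

    def canonical_newick(self) -> str:
        """Deterministic Newick string, rooted on the edge incident to the
        lexicographically smallest leaf, children sorted by smallest label."""
        if self.n_leaves == 1:
            (lab,) = self.leaf_labels
            return f"{lab};"
        root_lab = min(self._label_vertex)
        r = self._label_vertex[root_lab]
        (start,) = self._adj[r]

        def render(v: int, parent: int) -> Tuple[str, str]:
            if v in self._leaf_label:
                lab = self._leaf_label[v]
                return lab, lab
            parts = [render(w, v) for w in self._adj[v] if w != parent]
            parts.sort(key=lambda p: p[0])
            return parts[0][0], "(" + ",".join(p[1] for p in parts) + ")"

        if self.n_leaves == 2:
            other = self._leaf_label[start]
            return f"({root_lab},{other});"
        _, body = render(start, r)
        return f"({root_lab},{body});"

    def is_isomorphic(self, other: "UnrootedTree") -> bool:
        return (self.leaf_labels == other.leaf_labels
                and self.splits() == other.splits())

    # -- three-directional lazy cache ------------------------------------

    def assignment(self, v: int, away_from) -> RAG:
        """The DO assignment of ``v`` directed away from ``away_from`` (an
        incident edge or the neighbor vertex across it), memoized."""
        u = self._normalize_direction(v, away_from)
        return self._directed(v, u)[0]

    def _normalize_direction(self, v: int, away_from) -> int:
        if isinstance(away_from, frozenset):
            pair = set(away_from)
            if v not in pair:
                raise ValueError("away_from edge is not incident to v")
            (u,) = pair - {v} if len(pair) == 2 else (v,)
            return u
        return int(away_from)

    def side_label(self, v: int, u: int) -> str:
        """Smallest leaf label in the subtree hanging from ``v`` away from
        neighbor ``u``; memoized.  Used to order alignment operands so tree
        scores are invariant under re-parsing/relabeling of the topology."""
        key = (v, u)
        hit = self._lbl.get(key)
        if hit is not None:
            return hit
        stack = [key]
        while stack:
            w, z = stack[-1]
            if (w, z) in self._lbl:
                stack.pop()
                continue
            if w in self._leaf_label:
                self._lbl[(w, z)] = self._leaf_label[w]
                stack.pop()
                continue
            kids = [x for x in self._adj[w] if x != z]
            pending = [(x, w) for x in kids if (x, w) not in self._lbl]
            if pending:
                stack.extend(pending)
                continue
            self._lbl[(w, z)] = min(self._lbl[(x, w)] for x in kids)
            stack.pop()
        return self._lbl[key]

    def _ordered_kids(self, w: int, z: int) -> List[int]:
        kids = [x for x in self._adj[w] if x != z]
        kids.sort(key=lambda x: self.side_label(x, w))
        return kids

    def _directed(self, v: int, u: int) -> Tuple[RAG, int]:
        """(assignment RAG, accumulated subtree cost) of the subtree hanging
        from ``v`` away from neighbor ``u``.  Iterative post-order fill;
        children align in smallest-side-label order so ties in the DP break
        identically for every representation of the same topology."""
        key = (v, u)
        cached = self._dir.get(key)
        if cached is not None:
            return cached
        cost = self._require_bound()
        stack = [key]
        while stack:
            w, z = stack[-1]
            if (w, z) in self._dir:
                stack.pop()
                continue
            if w in self._leaf_label:
                self._dir[(w, z)] = (self._leaf_rag[w], 0)
                stack.pop()
                continue
            kids = self._ordered_kids(w, z)
            pending = [(x, w) for x in kids if (x, w) not in self._dir]
            if pending:
                stack.extend(pending)
                continue
            (r1, c1), (r2, c2) = self._dir[(kids[0], w)], self._dir[(kids[1], w)]
            res = align(r1, r2, cost)
            self._dir[(w, z)] = (res.median, c1 + c2 + res.cost)
            stack.pop()
        return self._dir[key]

    def edge_data(self, e: Edge) -> Tuple[RAG, int, int]:
        """(subdivision RAG, subdivision alignment cost, rooted length) at
        edge ``e``, memoized."""
        cached = self._edge.get(e)
        if cached is not None:
            return cached
        cost = self._require_bound()
        u, v = sorted(e)
        if not self.has_edge(e):
            raise ValueError(f"edge {sorted(e)} not in tree")
        if self.side_label(v, u) < self.side_label(u, v):
            u, v = v, u
        ru, cu = self._directed(u, v)
        rv, cv = self._directed(v, u)
        res = align(ru, rv, cost)
        entry = (res.median, res.cost, cu + cv + res.cost)
        self._edge[e] = entry
        return entry

    def rooted_length(self, e: Edge, cost: Optional[CostModel] = None) -> int:
        """Heuristic TAP length of the tree rooted at the subdivision vertex
        of ``e``: the total DO alignment cost accumulated in post-order."""
        if cost is not None and cost != self.cost_model:
            raise ValueError("cost model differs from the bound model")
        return self.edge_data(e)[2]

    def edge_break_length(self, e: Edge) -> int:
        """DO length of the edge itself (cost of aligning its two directed
        endpoint assignments); used for length-ordered edge breaking."""
        return self.edge_data(e)[1]

    def refresh_full(self) -> None:
        """Eagerly compute all three directions of every internal vertex and
        every edge's subdivision assignment (<= 3(n-2) + (2n-3) medians)."""
        self._require_bound()
        for e in self.edges():
            u, v = sorted(e)
            self._directed(u, v)
            self._directed(v, u)
        for e in self.edges():
            self.edge_data(e)

    def min_rooted_length(self) -> Tuple[int, Edge]:
        """Brute-force minimum rooted length over all edges (oracle helper)."""
        best = None
        for e in self.edges():
            ln = self.rooted_length(e)
            if best is None or ln < best[0]:
                best = (ln, e)
        return best

    # -- editing ----------------------------------------------------------

    def break_edge(self, e: Edge) -> Tuple["UnrootedTree", "UnrootedTree"]:
        """Remove edge ``e``, yielding the two components (leaf partition).

        Internal vertices left with degree 2 are collapsed.  Directional
        cache entries whose defining subtree did not contain ``e`` are
        carried over, so each component needs only O(|V|) new alignments to
        rescore.  Returns components ``(side of min(e), side of max(e))``.
        """
        if not self.has_edge(e):
            raise ValueError(f"edge {sorted(e)} not in tree")
        u, v = sorted(e)
        return self._component_after_break(u, v), self._component_after_break(v, u)

    def _component_after_break(self, u: int, v: int) -> "UnrootedTree":
        # BFS from u, never crossing (u, v); parent[w] = neighbor toward u.
        parent = {u: None}
        order = [u]
        for w in order:
            for x in self._adj[w]:
                if x not in parent and not (w == u and x == v):
                    parent[x] = w
                    order.append(x)
        comp = set(parent)
        adj = {w: [x for x in self._adj[w] if x in comp and
                   not (w == u and x == v)] for w in comp}
        collapse_pair: Optional[Tuple[int, int]] = None
        if u not in self._leaf_label:
            x, y = adj[u]
            adj[x] = [y if z == u else z for z in adj[x]]
            adj[y] = [x if z == u else z for z in adj[y]]
            del adj[u]
            comp.discard(u)
            collapse_pair = (x, y)
        t = UnrootedTree(
            adj,
            {w: lab for w, lab in self._leaf_label.items() if w in comp},
            {w: r for w, r in self._leaf_rag.items() if w in comp},
            self.cost_model,
        )
        # Carry the still-valid directional entries: for each vertex the one
        # pointing toward the break (its subtree looks away from the edit).
        for w in order:
            p = parent[w]
            if p is None or (collapse_pair is not None and p == u):
                continue
            ent = self._dir.get((w, p))
            if ent is not None:
                t._dir[(w, p)] = ent
        if collapse_pair is not None:
            x, y = collapse_pair
            for a, b in ((x, y), (y, x)):
                ent = self._dir.get((a, u))
                if ent is not None:
                    t._dir[(a, b)] = ent
        return t

    def attachment_edge_after_break(self, e: Edge, side_vertex: int) -> Optional[Edge]:
        """The edge of the broken-off component where ``e`` was attached: the
        merged edge if the endpoint collapsed, else the endpoint's remaining
        edge.  None for a single-vertex component."""
        u, v = sorted(e)
        end = u if side_vertex == u else v
        others = [x for x in self._adj[end] if x != (v if end == u else u)]
        if end in self._leaf_label:
            return _edge(end, others[0]) if others else None
        x, y = others
        return _edge(x, y)


def break_edge(t: UnrootedTree, e: Edge) -> Tuple[UnrootedTree, UnrootedTree]:
    return t.break_edge(e)


def join_trees(t: UnrootedTree, s: UnrootedTree,
               e: Optional[Edge], f: Optional[Edge]) -> UnrootedTree:
    """Join two trees: subdivide ``e`` of ``t`` with a new vertex ``x`` and
    ``f`` of ``s`` with ``x'``, and add the edge ``(x, x')``.  A single-vertex
    tree contributes its lone vertex directly (pass ``e=None``).  Inputs are
    not modified; valid cache entries carry over."""
    shared = t.leaf_labels & s.leaf_labels
    if shared:
        raise ValueError(f"trees share leaf labels: {sorted(shared)}")
    if t.cost_model != s.cost_model:
        raise ValueError("cost models differ between joined trees")

    adj: Dict[int, List[int]] = {}
    for src in (t, s):
        for w, nb in src._adj.items():
            adj[w] = list(nb)
    new_dir: Dict[Tuple[int, int], Tuple[RAG, int]] = dict(t._dir)
    new_dir.update(s._dir)

    def subdivide(src: UnrootedTree, edge: Optional[Edge]) -> int:
        if src.n_edges() == 0:
            (w,) = src._adj
            return w
        if edge is None or not src.has_edge(edge):
            raise ValueError("join edge missing from tree")
        p, q = sorted(edge)
        x = next(_vertex_ids)
        adj[p] = [x if z == q else z for z in adj[p]]
        adj[q] = [x if z == p else z for z in adj[q]]
        adj[x] = [p, q]
        for a, b in ((p, q), (q, p)):
            ent = src._dir.get((a, b))
            if ent is not None:
                new_dir[(a, x)] = ent
            new_dir.pop((a, b), None)
        return x

    x = subdivide(t, e)
    xp = subdivide(s, f)
    adj[x].append(xp)
    adj[xp].append(x)

    joined = UnrootedTree(
        adj,
        {**t._leaf_label, **s._leaf_label},
        {**t._leaf_rag, **s._leaf_rag},
        t.cost_model,
    )
    # Only entries pointing toward the new edge remain valid; drop the rest.
    parent = {x: xp, xp: x}
    order = [x, xp]
    for w in order:
        for z in adj[w]:
            if z not in parent:
                parent[z] = w
                order.append(z)
    joined._dir = {
        (w, z): ent for (w, z), ent in new_dir.items()
        if w in parent and parent[w] == z
    }
    return joined


def join_score(t: UnrootedTree, s: UnrootedTree,
               e: Optional[Edge], f: Optional[Edge]) -> int:
    """Rooted length, at the new edge's subdivision vertex, of the tree that
    ``join_trees(t, s, e, f)`` would produce — computed from the two
    components' edge caches with a single new alignment."""
    cost = t._require_bound()

    def side(src: UnrootedTree, edge: Optional[Edge]) -> Tuple[RAG, int]:
        if src.n_edges() == 0:
            (w,) = src._adj
            return src._leaf_rag[w], 0
        rag, _, ln = src.edge_data(edge)
        return rag, ln

    ra, ca = side(t, e)
    rb, cb = side(s, f)
    return ca + cb + rag_align.distance(ra, rb, cost)
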