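"""Tree-length bounding during search.

Direct optimization can produce a different tree length for each root
(subdivision vertex of each edge).  With a metric edit distance each of them
upper-bounds the optimum, so the minimum over roots is the preferable bound.
The *Non-exhaustive* (NE) mode keeps a single designated root; the
*Exhaustive* (E) mode folds in the extra roots that break and join steps
expose for free through the three-directional cache: the root at each broken
edge, and the root at each newly created join edge plus its adjacent edges.
If every edge of a tree is broken once during a search, the E bound equals
the minimum over all 2n-3 rooted lengths at no extra asymptotic cost.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .tree_core import Edge, UnrootedTree

__all__ = ["ScoreBound", "score_ne", "improve_on_break", "improve_on_join"]


@dataclass(frozen=True)
class ScoreBound:
    """Running minimum over the rooted lengths evaluated for one topology."""

    best_length: int
    best_root: Edge
    roots_evaluated: int = 1

    def improved_with(self, length: int, root: Edge) -> "ScoreBound":
        if length < self.best_length:
            return ScoreBound(length, root, self.roots_evaluated + 1)
        return replace(self, roots_evaluated=self.roots_evaluated + 1)


def score_ne(t: UnrootedTree, root: Edge,
             cost=None) -> ScoreBound:
    """Bound from the single designated root (a single maintained rooted view)."""
    return ScoreBound(t.rooted_length(root, cost), root, roots_evaluated=1)


def improve_on_break(bound: ScoreBound, t: UnrootedTree,
                     broken: Edge) -> ScoreBound:
    """Fold in the rooted length at the just-broken edge's subdivision
    vertex (O(|V|) via the three-directional cache)."""
    return bound.improved_with(t.rooted_length(broken), broken)


#: BFS edge-radius around the join edge whose roots are folded into the
#: Exhaustive bound at join time (a constant number of roots: <= 13).
JOIN_ROOT_RADIUS = 2


def improve_on_join(bound: Optional[ScoreBound], t: UnrootedTree,
                    new_edge: Edge) -> ScoreBound:
    """Fold in the rooted lengths at the just-created join edge and the
    edges within a small BFS radius of it — a constant number of extra
    roots around the changed region of the tree."""
    if bound is None:
        bound = score_ne(t, new_edge)
    else:
        bound = bound.improved_with(t.rooted_length(new_edge), new_edge)
    frontier = [new_edge]
    seen = {new_edge}
    for _ in range(JOIN_ROOT_RADIUS):
        nxt = []
        for e in frontier:
            for v in sorted(e):
                for w in t.neighbors(v):
                    f = frozenset((v, w))
                    if f not in seen:
                        seen.add(f)
                        nxt.append(f)
                        bound = bound.improved_with(t.rooted_length(f), f)
        frontier = nxt
    return bound
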