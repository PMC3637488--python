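"""TBR/SPR local search with the compared policy dimensions.

A search breaks an edge of the current tree (random or length-descending
order), then reconnects the two components at candidate edge pairs (SPR
holds the pruned component's original attachment; TBR reroots it across
edges within the reroot diameter of the break, in BFS order).  Candidates
are scored through the three-directional caches: the Non-exhaustive bound
is the rooted length at the new join edge, the Exhaustive bound folds in
the roots exposed by each break and join.  Union pruning restricts and
orders join pairs by the block-union lower bound.  Acceptance is
first-improvement (greedy) or Metropolis (simulated annealing with
geometric cooling); after every acceptance the union index is updated from
the best subdivision vertex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from .rag_align import CostModel, distance
from .tap_scoring import ScoreBound, improve_on_break, improve_on_join, score_ne
from .tree_core import Edge, UnrootedTree, join_score, join_trees
from .tree_build import _new_join_edge
from . import union_index as ui

__all__ = ["SearchPolicy", "SearchTrace", "MoveRecord", "annealing_accept",
           "sector_restrict", "union_admissible_joins", "tbr_neighborhood",
           "local_search"]


@dataclass(frozen=True)
class SearchPolicy:
    """Configuration of one local search."""

    neighborhood: str = "tbr"           # "tbr" | "spr"
    break_order: str = "random"         # "random" | "length"
    join_order: str = "random"          # "random" | "union"
    union_prune: bool = False
    union_threshold: float = 1.17
    mode: str = "e"                     # "e" | "ne"
    sector_diameter: Optional[int] = None   # None = infinity
    reroot_diameter: Optional[int] = None   # None = infinity
    annealing: Optional[Tuple[float, float]] = None  # (T0, coefficient)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.neighborhood not in ("tbr", "spr"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.break_order not in ("random", "length"):
            raise ValueError(f"unknown break order {self.break_order!r}")
        if self.join_order not in ("random", "union"):
            raise ValueError(f"unknown join order {self.join_order!r}")
        if self.mode not in ("e", "ne"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.union_threshold < 1:
            raise ValueError("union threshold must be >= 1")
        for d in (self.sector_diameter, self.reroot_diameter):
            if d is not None and d < 2:
                raise ValueError("diameters must be >= 2 (or None for no limit)")
        if self.annealing is not None:
            t0, coeff = self.annealing
            if t0 <= 0 or coeff <= 1:
                raise ValueError("annealing needs temperature > 0 and "
                                 "coefficient > 1")


@dataclass(frozen=True)
class MoveRecord:
    iteration: int
    broken: Tuple[int, ...]
    join_a: Optional[Tuple[int, ...]]
    join_b: Optional[Tuple[int, ...]]
    candidate_length: int
    accepted: bool
    roots_evaluated: int
    joins_evaluated: int


@dataclass
class SearchTrace:
    records: List[MoveRecord] = field(default_factory=list)
    final_tree: Optional[UnrootedTree] = None
    final_bound: Optional[ScoreBound] = None
    joins_evaluated: int = 0
    moves_accepted: int = 0

    def accepted_lengths(self) -> List[int]:
        return [r.candidate_length for r in self.records if r.accepted]

    def tsv(self) -> str:
        lines = ["iteration\tbroken\tjoin_a\tjoin_b\tcandidate_length"
                 "\taccepted\troots_evaluated\tjoins_evaluated"]
        for r in self.records:
            lines.append("\t".join(str(x) for x in (
                r.iteration, r.broken, r.join_a, r.join_b,
                r.candidate_length, int(r.accepted), r.roots_evaluated,
                r.joins_evaluated)))
        return "\n".join(lines)


def annealing_accept(delta: float, temperature: float,
                     rng: np.random.Generator) -> bool:
    """Metropolis rule: always accept non-worsening moves; accept a
    worsening move of size ``delta`` with probability exp(-delta/T)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta <= 0:
        return True
    return bool(rng.random() < math.exp(-delta / temperature))


def _edge_adjacency(t: UnrootedTree) -> Dict[Edge, List[Edge]]:
    out: Dict[Edge, List[Edge]] = {}
    for e in t.edges():
        adj = []
        for v in sorted(e):
            for w in t.neighbors(v):
                f = frozenset((v, w))
                if f != e:
                    adj.append(f)
        out[e] = adj
    return out


def edges_within(t: UnrootedTree, center, diameter: Optional[int],
                 adjacency: Optional[Dict[Edge, List[Edge]]] = None
                 ) -> List[Edge]:
    """Edges within BFS edge-distance ``diameter`` of ``center`` (an edge),
    in BFS order; all edges if ``diameter`` is None."""
    adjacency = adjacency or _edge_adjacency(t)
    if center is None or center not in adjacency:
        order = sorted(adjacency, key=lambda e: sorted(e))
        return order if diameter is None else order[:0]
    dist = {center: 0}
    queue = [center]
    order = [center]
    while queue:
        e = queue.pop(0)
        if diameter is not None and dist[e] >= diameter:
            continue
        for f in adjacency[e]:
            if f not in dist:
                dist[f] = dist[e] + 1
                queue.append(f)
                order.append(f)
    return order


def sector_restrict(t: UnrootedTree, diameter: Optional[int],
                    rng: np.random.Generator) -> List[Edge]:
    """Break scope for sectorial search: all edges when ``diameter`` is
    None, else the BFS ball of edges around a uniformly chosen center."""
    edges = sorted(t.edges(), key=lambda e: sorted(e))
    if diameter is None:
        return edges
    center = edges[int(rng.integers(len(edges)))]
    return edges_within(t, center, diameter)


def union_admissible_joins(edges_a: Sequence[Edge], edges_b: Sequence[Edge],
                           index_a: ui.UnionIndex, index_b: ui.UnionIndex,
                           threshold: float,
                           cost: CostModel) -> List[Tuple[Edge, Edge]]:
    """Join-edge pairs whose block-union lower bound is within ``threshold``
    times the minimum bound, in ascending bound order."""
    def edge_blocks(index, edge):
        # a single-vertex component is addressed as edge None: its one block
        if edge is None:
            return [0]
        return sorted({index.vertex_block[v] for v in sorted(edge)})

    pair_bounds = {}
    bound_cache: Dict[Tuple[int, int], int] = {}
    for ea in edges_a:
        for eb in edges_b:
            lo = None
            for ba in edge_blocks(index_a, ea):
                for bb in edge_blocks(index_b, eb):
                    key = (ba, bb)
                    if key not in bound_cache:
                        bound_cache[key] = distance(
                            index_a.blocks[ba].union,
                            index_b.blocks[bb].union, cost)
                    if lo is None or bound_cache[key] < lo:
                        lo = bound_cache[key]
            pair_bounds[(ea, eb)] = lo
    if not pair_bounds:
        return []
    overall = min(pair_bounds.values())
    cutoff = math.inf if math.isinf(threshold) else threshold * overall
    admitted = [(b, sorted(ea) if ea else [], sorted(eb) if eb else [],
                 (ea, eb))
                for (ea, eb), b in pair_bounds.items()
                if b <= cutoff]
    admitted.sort(key=lambda x: (x[0], x[1], x[2]))
    return [pair for _, _, _, pair in admitted]


@dataclass(frozen=True)
class Candidate:
    """One TBR/SPR move: the broken edge, the two reattachment edges, the
    candidate tree's bound, and the break-time root length of the source
    tree (used by Exhaustive bounding)."""

    broken: Edge
    join_a: Optional[Edge]
    join_b: Optional[Edge]
    tree: UnrootedTree
    bound: ScoreBound
    break_root_length: int


def tbr_neighborhood(t: UnrootedTree, policy: SearchPolicy,
                     rng: np.random.Generator,
                     index: Optional[ui.UnionIndex] = None
                     ) -> Iterator[Candidate]:
    """Yield TBR (or SPR) candidates of ``t`` in policy order, lazily.

    Edges are broken in random or DO-length-descending order; for each
    break, reconnections enumerate join-edge pairs: the component holding
    the smaller endpoint offers every edge (BFS-ordered around the break),
    the pruned component offers edges within the reroot diameter (SPR: only
    its original attachment edge).  Candidate trees are materialized with
    their caches carried over, and scored at the new join edge (plus its
    adjacent roots in Exhaustive mode).
    """
    cost = t._require_bound()
    scope = sector_restrict(t, policy.sector_diameter, rng)
    if policy.break_order == "random":
        scope = [scope[i] for i in rng.permutation(len(scope))]
    else:
        scope = sorted(scope,
                       key=lambda e: (-t.edge_break_length(e), sorted(e)))

    for broken in scope:
        if not t.has_edge(broken):
            continue
        break_root_length = t.rooted_length(broken)
        t1, t2 = t.break_edge(broken)
        if t1.n_leaves + t2.n_leaves < 4:
            continue
        u, v = sorted(broken)
        attach2 = t.attachment_edge_after_break(broken, v)
        attach1 = t.attachment_edge_after_break(broken, u)

        edges1 = (edges_within(t1, attach1, None) if t1.n_edges() else [None])
        if t2.n_edges() == 0:
            edges2 = [None]
        elif policy.neighborhood == "spr":
            edges2 = [attach2]
        else:
            edges2 = edges_within(t2, attach2, policy.reroot_diameter)

        if policy.union_prune or policy.join_order == "union":
            i1 = ui.build_index(t1, cost)
            i2 = ui.build_index(t2, cost)
            thr = policy.union_threshold if policy.union_prune else math.inf
            pairs = union_admissible_joins(edges1, edges2, i1, i2, thr, cost)
        else:
            pairs = [(e1, e2) for e1 in edges1 for e2 in edges2]
            if policy.join_order == "random":
                pairs = [pairs[i] for i in rng.permutation(len(pairs))]

        for e1, e2 in pairs:
            if e1 == attach1 and e2 == attach2:
                continue  # reproduces t itself
            cand = join_trees(t1, t2, e1, e2)
            new_edge = _new_join_edge(cand, t1, t2)
            if policy.mode == "e":
                bound = improve_on_join(None, cand, new_edge)
            else:
                bound = score_ne(cand, new_edge)
            yield Candidate(broken, e1, e2, cand, bound, break_root_length)


def local_search(t0: UnrootedTree, policy: SearchPolicy,
                 cost: Optional[CostModel] = None) -> SearchTrace:
    """Run a first-improvement (or simulated-annealing) local search from
    ``t0`` and return its trace with the final tree and bound."""
    if cost is not None and t0.cost_model is None:
        raise ValueError("bind sequences to the tree before searching")
    t = t0
    rng = np.random.default_rng(policy.seed)
    ne_root = t.leaf_edge(min(t.leaf_labels))
    bound = score_ne(t, ne_root)
    trace = SearchTrace()
    index: Optional[ui.UnionIndex] = None
    temperature = policy.annealing[0] if policy.annealing else None
    coeff = policy.annealing[1] if policy.annealing else None

    iteration = 0
    while True:
        improved_this_pass = False
        restart = False
        for cand in tbr_neighborhood(t, policy, rng, index):
            iteration += 1
            trace.joins_evaluated += 1
            if policy.mode == "e":
                bound = bound.improved_with(cand.break_root_length,
                                            cand.broken)
            delta = cand.bound.best_length - bound.best_length
            if policy.annealing is None or temperature < 1.0:
                # greedy (and the frozen endgame of annealing): strict
                # improvement only, so equal-length moves cannot cycle
                accept = delta < 0
                if policy.annealing is not None:
                    temperature *= (1.0 - 1.0 / coeff)
            else:
                accept = annealing_accept(delta, temperature, rng)
                temperature *= (1.0 - 1.0 / coeff)
            trace.records.append(MoveRecord(
                iteration, tuple(sorted(cand.broken)),
                tuple(sorted(cand.join_a)) if cand.join_a else None,
                tuple(sorted(cand.join_b)) if cand.join_b else None,
                cand.bound.best_length, accept,
                cand.bound.roots_evaluated, trace.joins_evaluated))
            if accept:
                t = cand.tree
                bound = cand.bound
                trace.moves_accepted += 1
                if policy.union_prune or policy.join_order == "union":
                    if index is None:
                        index = ui.build_index(t, t.cost_model,
                                               bound.best_root)
                    else:
                        index = ui.update_after_accept(index, t,
                                                       bound.best_root)
                if delta < 0:
                    improved_this_pass = True
                restart = True
                break
        if restart:
            continue
        if policy.annealing is not None and temperature >= 1.0:
            continue
        if not improved_this_pass:
            break

    trace.final_tree = t
    trace.final_bound = bound
    return trace
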