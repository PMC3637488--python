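"""Scaled-down reproductions of the algorithm comparisons.

The full study compared builders and refinement policies on 50-leaf
simulations with 500-residue roots and hundreds of repetitions.  These
protocols rerun the same comparisons at desk scale — 10-leaf trees,
100-residue roots, tens of seeds — preserving the qualitative questions:
does the Exhaustive bound beat the Non-exhaustive one, does the MST
addition sequence beat RAS, and does Union-pruning save join evaluations
without costing tree length?
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np

from .local_search import SearchPolicy, local_search
from .rag_align import CostModel, leaf_to_rag
from .simulate import SimulationConfig, simulate_dataset
from .tree_build import mst_addition, pairwise_distances, ras, wagner_build

__all__ = ["ComparisonResult", "compare_e_vs_ne", "compare_mst_vs_ras",
           "compare_union_pruning"]

DEFAULT_COST = CostModel(1, 1, 0)


@dataclass
class ComparisonResult:
    """Per-seed paired measurements from one scaled-down comparison."""

    label_a: str
    label_b: str
    values_a: List[float]
    values_b: List[float]
    extra: Optional[Dict[str, List[float]]] = None

    @property
    def mean_a(self) -> float:
        return float(np.mean(self.values_a))

    @property
    def mean_b(self) -> float:
        return float(np.mean(self.values_b))


def _dataset_rags(seed: int, n_leaves: int, branch: float,
                  root_length: int) -> Dict[str, object]:
    cfg = SimulationConfig(n_leaves=n_leaves, mean_branch_length=branch,
                           root_length=root_length, seed=seed)
    _, records = simulate_dataset(cfg)
    return {r.id: leaf_to_rag(r) for r in records}


def compare_e_vs_ne(n_seeds: int = 20, n_leaves: int = 10,
                    branch: float = 0.2, root_length: int = 100,
                    cost: CostModel = DEFAULT_COST,
                    master_seed: int = 0) -> ComparisonResult:
    """TBR refinement with Exhaustive vs Non-exhaustive bounding on paired
    simulated datasets (same initial tree, same search seed)."""
    e_vals, ne_vals = [], []
    for i in range(n_seeds):
        seed = master_seed * 10007 + i
        rags = _dataset_rags(seed, n_leaves, branch, root_length)
        t0 = wagner_build(rags, ras(sorted(rags),
                                    np.random.default_rng(seed)), cost)
        for mode, sink in (("e", e_vals), ("ne", ne_vals)):
            trace = local_search(t0, SearchPolicy(seed=seed, mode=mode))
            sink.append(trace.final_bound.best_length)
    return ComparisonResult("e", "ne", e_vals, ne_vals)


def compare_mst_vs_ras(n_seeds: int = 30, n_leaves: int = 10,
                       branch: float = 0.1, root_length: int = 100,
                       cost: CostModel = DEFAULT_COST,
                       master_seed: int = 0) -> ComparisonResult:
    """Initial Wagner builds with the MST-derived addition sequence vs
    random addition sequences, scored as the minimum over all roots."""
    mst_vals, ras_vals = [], []
    for i in range(n_seeds):
        seed = master_seed * 10007 + i
        rags = _dataset_rags(seed, n_leaves, branch, root_length)
        labels, mat = pairwise_distances(rags, cost)
        rng = np.random.default_rng(seed)
        q = mst_addition(labels, mat, rng, iteration=i)
        t_mst = wagner_build(rags, q, cost)
        mst_vals.append(t_mst.min_rooted_length()[0])
        t_ras = wagner_build(rags, ras(labels, np.random.default_rng(seed)),
                             cost)
        ras_vals.append(t_ras.min_rooted_length()[0])
    return ComparisonResult("mst", "ras", mst_vals, ras_vals)


def compare_union_pruning(n_seeds: int = 20, n_leaves: int = 10,
                          branch: float = 0.1, root_length: int = 100,
                          cost: CostModel = DEFAULT_COST,
                          master_seed: int = 0) -> ComparisonResult:
    """Union-pruned TBR (threshold 1.17, union-ascending join order) vs
    unpruned TBR on paired instances; values are final lengths, with the
    per-seed join-evaluation counts in ``extra``."""
    pruned_len, plain_len = [], []
    pruned_joins, plain_joins = [], []
    for i in range(n_seeds):
        seed = master_seed * 10007 + i
        rags = _dataset_rags(seed, n_leaves, branch, root_length)
        t0 = wagner_build(rags, ras(sorted(rags),
                                    np.random.default_rng(seed)), cost)
        tr_p = local_search(t0, SearchPolicy(
            seed=seed, mode="e", union_prune=True, join_order="union"))
        pruned_len.append(tr_p.final_bound.best_length)
        pruned_joins.append(tr_p.joins_evaluated)
        tr_u = local_search(t0, SearchPolicy(seed=seed, mode="e"))
        plain_len.append(tr_u.final_bound.best_length)
        plain_joins.append(tr_u.joins_evaluated)
    return ComparisonResult(
        "union_pruned", "unpruned", pruned_len, plain_len,
        extra={"pruned_joins": pruned_joins, "plain_joins": plain_joins})
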