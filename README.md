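# gtapsearch

Local search heuristics for the **Generalized Tree Alignment Problem**
(GTAP): given unaligned DNA sequences, jointly estimate a binary phylogeny
and its implied ancestral sequences under maximum parsimony with affine gap
costs. The GTAP is the Steiner tree problem under the sequence edit
distance; it is NP-hard, so practical analysis rests on the quality of the
local search. This package is for researchers studying those heuristics:
it implements the full toolkit — direct-optimization scoring on reduced
alignment graphs, efficient rescoring during tree rearrangement, improved
tree-length bounding, union-based search pruning, and several initial-tree
builders — together with a synthetic sequence-evolution generator and an
experiment-grid runner for comparing the algorithms.

## The model

A candidate solution is an unrooted binary tree `T` whose leaves carry the
input sequences. Edit costs are integers: `substitution` per mismatched
column, and `gap_opening + L × indel` for a gap of length `L`. Scoring is
heuristic **direct optimization** (DO): rooted at the subdivision vertex of
any edge, each internal vertex is assigned a *reduced alignment graph*
(RAG) — an ordered sequence of symbol-set columns over `{A,C,G,T,indel}`
compactly representing a set of candidate ancestral sequences — via
affine-gap pairwise alignment of its children in post-order, and the tree
length is the accumulated alignment cost

    len(T, r) = Σ_v d(A(left(v)), A(right(v)))

where `d` is the affine-gap DO distance. With a metric cost every root
yields an upper bound of the Steiner optimum, so the search tracks the
minimum over the roots it sees. The toolkit's core devices:

- **Three-directional assignments** — each internal vertex caches its DO
  assignment in all three directions away from its incident edges, lazily
  and memoized, so that after breaking or joining trees only O(|V|) new
  alignments are needed to rescore the whole TBR neighborhood.
- **Exhaustive bounding (E)** — fold in the rooted lengths that breaks and
  joins expose for free; after breaking every edge once, the bound equals
  the minimum over all `2n−3` roots. Non-exhaustive (NE) keeps a single
  root, as older implementations did.
- **Union-pruning** — partition vertices into connected blocks of ≤ 12,
  each carrying the RAG union of its members; the DO distance between two
  block unions lower-bounds the best member-pair distance, so join
  candidates whose block distance exceeds 1.17× the minimum are skipped.
- **Builders** — Wagner construction with random (RAS) or MST-derived
  addition sequences and beam lookahead, plus deterministic neighbor
  joining.
- **Searches** — TBR/SPR with random or length-sorted break orders, union
  or random join orders, sector and reroot diameters, and optional
  simulated annealing.

## Worked example

Simulate 8 sequences on a random tree (60-residue root, mean branch length
0.1, indels up to 5 sites), build a neighbor-joining starting tree, and
refine it with union-pruned Exhaustive TBR:

```
$ gtapsearch simulate --leaves 8 --branch 0.1 --max-gap 5 \
      --root-length 60 --seed 7 --out demo.fasta
wrote 8 sequences to demo.fasta; true tree in demo.true.nwk

$ gtapsearch build demo.fasta --method nj | head -1 > start.nwk
$ gtapsearch build demo.fasta --method nj
(t0,((t1,((t2,t7),(t3,(t5,t6)))),t4));
# length	109

$ gtapsearch search demo.fasta --tree start.nwk --mode e \
      --union-prune --join-order union --seed 3
(t0,(((t1,(t3,(t5,t6))),(t2,t7)),t4));
# length	106
```

The reported length is the total parsimony cost of the implied alignment —
substitutions plus affine-weighted gaps — minimized over root positions.
The neighbor-joining tree costs 109; TBR refinement moves the `(t2,t7)`
cherry to sit with `t1`, reaching a tree of length 106 (a Wagner build
with a random addition sequence finds the same tree directly on this easy
instance). `gtapsearch score demo.fasta start.nwk` rescores any Newick
tree the same way (`length 109`, with the best root edge). A `grid`
subcommand runs
declared (builder × search × dataset × repetition) grids and tabulates
per-configuration minimum and mean lengths.

The library mirrors the CLI: `gtapsearch.align`/`distance`/`merge_union`
(RAG core), `UnrootedTree` with `break_edge`/`join_trees` and cached
`rooted_length`, `wagner_build`/`nj_build`, `SearchPolicy` +
`local_search`, and `simulate_dataset`.

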