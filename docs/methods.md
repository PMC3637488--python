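# Methods

`gtapsearch` implements heuristic local search for the Generalized Tree
Alignment Problem (GTAP): given unaligned DNA sequences at the leaves, find
jointly a binary tree topology and implied ancestral sequences minimizing
the total edit cost over the edges — the Steiner tree problem under the
sequence edit distance. This note documents the model, the numerical
choices, and the limits of what the test suite demonstrates.

## Scoring model

**Cost model.** Integer parsimony costs: `substitution` per mismatched
aligned column, `indel` per gapped residue, `gap_opening` per contiguous
gap run, so a gap of length L costs `gap_opening + L * indel`. Construction
verifies that the induced distance on single residues is metric (it is for
all nonnegative integer parameters; the check is kept explicit because
root-invariance of the tree length depends on it). Four presets are used
throughout: (1,1,0), (1,2,0), (2,1,1), (3,1,2).

**RAGs.** A reduced alignment graph is an ordered sequence of columns, each
a nonempty subset of {A,C,G,T,indel}, stored as uint8 bitmasks. A plain
sequence is *contained* in a RAG if it can be spelled by choosing one
symbol per column in order and deleting chosen indels. Leaf sequences
become RAGs of singleton (or IUPAC ambiguity-set) columns with no indels.

**Alignment.** Two RAGs are aligned by a three-state Gotoh dynamic program
over columns: a column pair costs 0 if the base sets intersect, else
`substitution`; gap runs cost `gap_opening + length * indel`. Two
conventions matter and are deliberate:

- *Skippable columns are free.* Gapping a column that already contains the
  indel symbol costs no extension, and a run that **enters** at such a
  column also pays no opening. This makes the DO distance between two RAG
  unions a true heuristic lower bound on the distance between their
  closest contained sequences (measured 0 violations in 600 random block
  pairs across all presets, versus up to 25% violations when the opening
  is charged unconditionally). On gap-free inputs — every leaf-vs-leaf
  comparison — the run cost reduces exactly to `gap_opening + L * indel`,
  so plain-sequence alignment remains the exact affine edit distance.
- *Deterministic tie-breaking.* Equal-cost predecessors resolve
  diagonal-first, then gap-in-second, then gap-in-first, so medians are
  bit-reproducible across platforms.

The median RAG has one column per aligned pair: set intersection when it
contains a base, else union; the indel symbol is added only at columns
aligned against a gap, and a column can never be {indel} alone. The DP is
O(|a|·|b|); the kernel is numba-jitted with a pure-Python fallback.

**Union.** `merge_union(a, b)` aligns `a` and `b` and emits, per aligned
position, the set union of the `a` column, `b` column, and median column,
adding the indel symbol where either input was gapped so skipped inputs
remain recoverable. Consequences held as binding contracts (and checked on
1000 random merges): every sequence contained in either input or the
median is contained in the union (containment), and at most |a|+|b|
columns are emitted (linearity).

## Tree scoring: the three-directional lazy cache

An unrooted binary tree is scored by direct optimization from a root — the
subdivision vertex of any edge. With a metric cost the minimum over roots
is the natural tree-length bound, and every root can be served from one
shared structure: for each directed edge (v→u) the cache holds the RAG and
accumulated cost of the subtree hanging from v away from u (three entries
per internal vertex). The rooted length at edge (u,v) is then
`cost(u→v) + cost(v→u) + d(A(u→v), A(v→u))`. Entries are computed lazily
and memoized; a full refresh performs at most `3(n−2) + (2n−3)` median
computations.

Break and join operations carry over exactly the entries whose defining
subtree did not contain the edited edge (those directed toward the edit)
and remap entries across the collapsed or subdivided vertex. The suite
verifies the two efficiency claims by instrumentation: after one refresh,
scoring both components of *every* possible single-edge break costs at
most 2 new alignments per break, and scoring all join-edge pairs of two
refreshed components costs exactly one new alignment per pair. Soundness
(no stale cache reads) is checked against cache-free recomputation over
random break/join chains.

## Bounding: Exhaustive vs Non-exhaustive

Non-exhaustive (NE) keeps a single designated root — the edge created by
the most recent join. Exhaustive (E) folds in the roots that the search
exposes for free: the root at each broken edge (one O(|V|) evaluation per
break) and, at each join, the new edge's root plus its at most four
adjacent edges' roots. If a search breaks every edge of a tree once, the E
bound provably equals the minimum over all 2n−3 rooted lengths; the suite
checks this and E ≤ NE on matched candidate enumerations. Which extra
roots a join evaluates is an open design point; adjacent edges were chosen
as the smallest set that keeps the constant-factor guarantee while
covering the neighborhood of the changed region.

## Union index and pruning

Tree vertices are partitioned into connected blocks of at most 12 vertices
by a greedy bottom-up pass over the rooted traversal (a vertex absorbs its
children's still-open blocks while the bound allows). Each block carries
the fold of `merge_union` over its members' root-directed assignments,
memoized by member-assignment fingerprint so that re-rooting after an
accepted move only recomputes blocks the move touched. A single-leaf
component is a one-block union of its own — this matters in TBR, where
leaf-edge breaks dominate candidate counts.

Join candidates (edge pairs) are ranked by the DO distance between the
blocks at their endpoints; with pruning on, pairs whose bound exceeds 1.17
times the minimum bound are discarded, and candidates are tried in
ascending bound order. The threshold multiplies the minimum block bound
(not the current tree length); at threshold infinity the pruned search
reproduces the unpruned move sequence bit-for-bit under shared seeds.

## Search

TBR breaks an edge (random or DO-length-descending order, the edge length
being its subdivision alignment cost) and reconnects the two components at
candidate edge pairs; SPR fixes the pruned component's original attachment
edge. Reroot and sector diameters bound, respectively, the BFS ball of
reattachment edges around the break and the BFS ball of breakable edges
around a random center. Acceptance is first-improvement with strict
improvement (equal-length candidates are rejected, so greedy runs cannot
cycle); simulated annealing uses the Metropolis rule `exp(−Δ/T)` with
geometric cooling `T ← T(1 − 1/c)` per proposal — the coefficient
c ∈ {12, 50, 250, 500} orders schedules from fast to slow, and once T
drops below 1 the run finishes with strict-improvement passes so
termination is guaranteed. Any monotone cooling parameterization would
satisfy the published description; this one was chosen for its one-line
semantics.

Wagner construction adds leaves in an addition-sequence order, trying each
join edge of each retained partial tree and keeping the `lookahead` best
(beam interpretation of the lookahead parameter; k=1 is classic greedy).
The MST addition sequence is the BFS order of the leaf minimum spanning
tree (Prim from the lexicographically smallest label, ties by label), with
iteration k applying k left-to-right passes of independent adjacent swaps
at probability 0.5. Neighbor joining is implemented directly with
deterministic tie-breaking (smallest Q, then smallest label pair) so its
output is invariant under input permutation; it is cross-checked against
scikit-bio's implementation in the suite.

## Synthetic data

The generator emulates an indel-aware evolution simulation: a uniform
random root sequence (default 500 residues) evolves along a random binary
tree (sequential coalescence topology, i.i.d. exponential branch lengths)
under Jukes–Cantor substitutions at rate 1.5, with indel events at rate
0.1 per site per unit branch length, insertion/deletion equiprobable, and
lengths from a power law (exponent 1.7) truncated at a configurable
maximum gap in {1, 2, 5, 10, 15}. Mean branch length ∞ is a saturation
flag producing independent uniform leaf sequences. Defaults follow the
study design this toolkit replicates (50 leaves, root length 500); the
substitution model is the simplest one consistent with a single stated
rate, and the indel rate and power-law exponent are configurable because
the study names the family but not those values.

What the generator does **not** emulate: rate heterogeneity across sites,
GTR-style unequal exchangeabilities or base frequencies, overlapping-event
edge cases of event-time simulation, and alignment-confounding repeats.
Passing tests therefore demonstrate correctness of the search machinery
and the direction of algorithm comparisons under clean, homogeneous
evolution — not performance claims about real data.

## Problem sizes in the checks

The distributed checks run at desk scale, chosen once as representative:
alignment exactness on 2,000 random pairs (lengths ≤ 12) against an
independent aligner; union theorems on 1,000 merges; three-directional
equality on ~100 random trees of up to 8 leaves; optimum recovery on n=5
instances (sequence lengths 6–12, all 15 starting topologies per instance,
per-start seeds); and the qualitative comparisons on 10-leaf,
100-residue-root simulations with 12–30 paired seeds (Exhaustive vs
Non-exhaustive at branch length 0.2; MST vs RAS and Union-pruning at 0.1,
where those effects are expected to show). The full published grid —
50-leaf trees, 100 repetitions, 34 build and 208 refinement
configurations — is represented by its scheduling arithmetic (102,000
builds, 624,000 refinements) and by the `grid` runner, which reproduces
the protocol at any scale.

## Known limitations

- The one-move TBR neighborhood of a 5-leaf tree contains 13 of the 15
  topologies (verified exhaustively); claims that single-move TBR spans
  the whole space at n=5 are false and are not asserted.
- Greedy first-improvement search converges to heuristic local optima in
  a few percent of starts on rugged small instances; the recovery-rate
  check treats those as expected failures and asserts the rate, not
  universality.
- The union lower bound is heuristic: it is validated statistically (0
  violations in the suite's samples), not proven, for RAGs that already
  contain indel columns.
- Tree lengths are heuristic upper bounds of the true Steiner optimum
  (verified against exact enumeration only at n ≤ 4, sequence length ≤ 2).
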