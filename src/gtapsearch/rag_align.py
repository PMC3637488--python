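"""Affine-gap direct-optimization (DO) core on reduced alignment graphs.

A *reduced alignment graph* (RAG) is an ordered sequence of columns, each a
nonempty subset of ``{A, C, G, T, indel}``.  A plain sequence is *contained*
in a RAG if it can be produced by choosing one symbol per column, in order,
and deleting the chosen indels.  RAGs compactly represent sets of sequences;
aligning two RAGs with an affine gap penalty estimates the edit distance
between the closest pair of sequences they contain, and the median RAG of
that alignment represents candidate ancestral sequences.  This is the
scoring primitive of direct optimization for the tree alignment problem.

Columns are stored as integer bitmasks (A=1, C=2, G=4, T=8, indel=16), so a
RAG is a ``numpy.uint8`` vector and the dynamic program runs on flat integer
arrays.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "A_BIT", "C_BIT", "G_BIT", "T_BIT", "GAP_BIT", "BASE_MASK",
    "IUPAC_MASKS", "CostModel", "PRESET_COST_MODELS", "RAG",
    "AlignmentResult", "leaf_to_rag", "align", "distance", "merge_union",
    "contains", "counters",
]

A_BIT, C_BIT, G_BIT, T_BIT, GAP_BIT = 1, 2, 4, 8, 16
BASE_MASK = A_BIT | C_BIT | G_BIT | T_BIT

#: IUPAC nucleotide codes as base bitmasks.  U is treated as T.
IUPAC_MASKS = {
    "A": A_BIT, "C": C_BIT, "G": G_BIT, "T": T_BIT, "U": T_BIT,
    "R": A_BIT | G_BIT, "Y": C_BIT | T_BIT, "S": C_BIT | G_BIT,
    "W": A_BIT | T_BIT, "K": G_BIT | T_BIT, "M": A_BIT | C_BIT,
    "B": C_BIT | G_BIT | T_BIT, "D": A_BIT | G_BIT | T_BIT,
    "H": A_BIT | C_BIT | T_BIT, "V": A_BIT | C_BIT | G_BIT,
    "N": BASE_MASK,
}

_BIT_CHARS = {A_BIT: "A", C_BIT: "C", G_BIT: "G", T_BIT: "T", GAP_BIT: "-"}


@dataclass
class _Counters:
    """Instrumentation: how many DP alignments / medians / union merges ran."""

    alignments: int = 0
    medians: int = 0
    union_merge_steps: int = 0

    def reset(self) -> None:
        self.alignments = 0
        self.medians = 0
        self.union_merge_steps = 0

    def snapshot(self) -> Tuple[int, int, int]:
        return (self.alignments, self.medians, self.union_merge_steps)


counters = _Counters()


@dataclass(frozen=True)
class CostModel:
    """Integer edit costs: substitution per mismatched column, indel per
    gapped residue (gap extension), and gap_opening per contiguous gap run.

    A gap of length L costs ``gap_opening + L * indel``.
    """

    substitution: int
    indel: int
    gap_opening: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution", "indel", "gap_opening"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.substitution == 0 and self.indel == 0:
            raise ValueError("substitution and indel costs cannot both be zero")
        self._check_metric()

    def gap_cost(self, length: int) -> int:
        return 0 if length == 0 else self.gap_opening + length * self.indel

    def _check_metric(self) -> None:
        # Distance induced on single residues (and the empty sequence):
        # unequal residues cost min(substitution, two single-residue gaps);
        # residue vs empty costs one opened gap of length 1.
        sub_eff = min(self.substitution, 2 * self.gap_cost(1))
        pts = ["A", "C", "G", "T", ""]

        def d(x: str, y: str) -> int:
            if x == y:
                return 0
            if x and y:
                return sub_eff
            return self.gap_cost(1)

        for x, y, z in itertools.product(pts, repeat=3):
            if d(x, z) > d(x, y) + d(y, z):
                raise ValueError(
                    f"cost model {self} induces a non-metric residue distance"
                )


#: The four (substitution, indel, gap_opening) combinations used throughout.
PRESET_COST_MODELS = (
    CostModel(1, 1, 0),
    CostModel(1, 2, 0),
    CostModel(2, 1, 1),
    CostModel(3, 1, 2),
)


class RAG:
    """Immutable ordered sequence of symbol-set columns (uint8 bitmasks)."""

    __slots__ = ("cols", "_hash")

    def __init__(self, cols: Iterable[int] | np.ndarray):
        arr = np.asarray(cols, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("RAG columns must be a 1-d sequence")
        if arr.size:
            if (arr == 0).any():
                raise ValueError("RAG columns must be nonempty symbol sets")
            if (arr == GAP_BIT).any():
                raise ValueError("a RAG column cannot be the indel symbol alone")
        arr.setflags(write=False)
        object.__setattr__(self, "cols", arr)
        object.__setattr__(self, "_hash", hash(arr.tobytes()))

    @classmethod
    def from_sequence(cls, residues: str) -> "RAG":
        try:
            masks = [IUPAC_MASKS[ch] for ch in residues.upper()]
        except KeyError as exc:
            raise ValueError(f"not an IUPAC DNA code: {exc.args[0]!r}") from None
        return cls(masks)

    def __len__(self) -> int:
        return int(self.cols.size)

    def __iter__(self) -> Iterator[int]:
        return iter(int(c) for c in self.cols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RAG):
            return NotImplemented
        return self.cols.shape == other.cols.shape and bool(
            (self.cols == other.cols).all()
        )

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"RAG({self.dump()!r})"

    def column_symbols(self, i: int) -> str:
        """Symbols of column ``i`` in fixed A,C,G,T,- order."""
        c = int(self.cols[i])
        return "".join(ch for bit, ch in _BIT_CHARS.items() if c & bit)

    def dump(self) -> str:
        """One token per column, sorted symbols, indel printed as ``-``."""
        return " ".join(self.column_symbols(i) for i in range(len(self)))


EMPTY_RAG = RAG([])


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of aligning two RAGs: optimal affine cost, the median RAG, and
    the two gapped column sequences (``None`` marks a gap)."""

    cost: int
    median: RAG
    aligned_a: Tuple[Optional[int], ...]
    aligned_b: Tuple[Optional[int], ...]


def leaf_to_rag(record) -> RAG:
    """Encode a :class:`SequenceRecord`-like object (``.residues``) as a RAG."""
    residues = record.residues if hasattr(record, "residues") else str(record)
    return RAG.from_sequence(residues)


# ---------------------------------------------------------------------------
# Gotoh three-state DP.  States: 0 = M (column vs column), 1 = X (consume a
# column of `a` against a gap in `b`), 2 = Y (gap in `a`).  Equal-cost
# predecessors break diagonal-first (M), then X, then Y, so medians are
# reproducible.  Gapping a column that already contains the indel symbol is
# free (no extension; no opening when the run enters at such a column), so
# sequences "skipped" inside a RAG can be recovered at zero cost — this is
# what makes union distances lower-bound member distances.  On gap-free
# inputs the run cost is exactly gap_opening + length * indel.
# ---------------------------------------------------------------------------

_INF = np.int64(1) << 40


def _dp_python(a, b, sub, ind, go):
    n, m = a.shape[0], b.shape[0]
    M = np.full((n + 1, m + 1), _INF, np.int64)
    X = np.full((n + 1, m + 1), _INF, np.int64)
    Y = np.full((n + 1, m + 1), _INF, np.int64)
    pM = np.full((n + 1, m + 1), -1, np.int8)
    pX = np.full((n + 1, m + 1), -1, np.int8)
    pY = np.full((n + 1, m + 1), -1, np.int8)
    M[0, 0] = 0
    for i in range(1, n + 1):
        skip = a[i - 1] & GAP_BIT
        e = 0 if skip else ind
        o = 0 if skip else go
        best, p = M[i - 1, 0] + o, 0
        if X[i - 1, 0] < best:
            best, p = X[i - 1, 0], 1
        X[i, 0] = best + e
        pX[i, 0] = p
    for j in range(1, m + 1):
        skip = b[j - 1] & GAP_BIT
        e = 0 if skip else ind
        o = 0 if skip else go
        best, p = M[0, j - 1] + o, 0
        if Y[0, j - 1] < best:
            best, p = Y[0, j - 1], 2
        Y[0, j] = best + e
        pY[0, j] = p
    for i in range(1, n + 1):
        ca = a[i - 1]
        skipa = ca & GAP_BIT
        ea = 0 if skipa else ind
        oa = 0 if skipa else go
        for j in range(1, m + 1):
            cb = b[j - 1]
            d = 0 if (ca & cb & BASE_MASK) else sub
            best, p = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] < best:
                best, p = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] < best:
                best, p = Y[i - 1, j - 1], 2
            M[i, j] = best + d
            pM[i, j] = p

            best, p = M[i - 1, j] + oa, 0
            if X[i - 1, j] < best:
                best, p = X[i - 1, j], 1
            if Y[i - 1, j] + oa < best:
                best, p = Y[i - 1, j] + oa, 2
            X[i, j] = best + ea
            pX[i, j] = p

            skipb = cb & GAP_BIT
            eb = 0 if skipb else ind
            ob = 0 if skipb else go
            best, p = M[i, j - 1] + ob, 0
            if X[i, j - 1] + ob < best:
                best, p = X[i, j - 1] + ob, 1
            if Y[i, j - 1] < best:
                best, p = Y[i, j - 1], 2
            Y[i, j] = best + eb
            pY[i, j] = p
    return M, X, Y, pM, pX, pY


def _compile_kernel():
    try:  # pragma: no cover - exercised indirectly
        import numba
    except Exception:  # pragma: no cover
        return _dp_python
    try:
        kernel = numba.njit(cache=False, nogil=True)(_dp_python)
        # force compilation once so failures fall back cleanly
        z = np.zeros(1, np.uint8) + 1
        kernel(z, z, 1, 1, 0)
        return kernel
    except Exception:  # pragma: no cover
        return _dp_python


_dp_kernel = _compile_kernel()


def _dp(a: RAG, b: RAG, cost: CostModel):
    counters.alignments += 1
    return _dp_kernel(
        a.cols, b.cols, cost.substitution, cost.indel, cost.gap_opening
    )


def _final_state(M, X, Y, n, m) -> Tuple[int, int]:
    best, state = M[n, m], 0
    if X[n, m] < best:
        best, state = X[n, m], 1
    if Y[n, m] < best:
        best, state = Y[n, m], 2
    return int(best), state


def _traceback(a, b, mats) -> list:
    M, X, Y, pM, pX, pY = mats
    n, m = a.cols.shape[0], b.cols.shape[0]
    _, state = _final_state(M, X, Y, n, m)
    ptr = (pM, pX, pY)
    steps = []
    i, j = n, m
    while i > 0 or j > 0:
        steps.append((state, i, j))
        prev = int(ptr[state][i, j])
        if state == 0:
            i, j = i - 1, j - 1
        elif state == 1:
            i -= 1
        else:
            j -= 1
        state = prev
    steps.reverse()
    return steps


def _median_column(ca: int, cb: int) -> int:
    inter = ca & cb
    if inter & BASE_MASK:
        return inter
    return (ca | cb) & ~GAP_BIT


def align(a: RAG, b: RAG, cost: CostModel) -> AlignmentResult:
    """Affine-gap DO alignment of two RAGs.

    A column pair costs 0 when the base sets intersect, else ``substitution``;
    a gap run costs ``gap_opening + length * indel`` (extensions against
    columns containing the indel symbol are free).  The median has one column
    per aligned pair: set intersection when it contains a base, else union,
    with the indel symbol added to columns aligned against a gap.  On
    gap-free singleton-column inputs the cost is the exact affine edit
    distance between the plain sequences.
    """
    mats = _dp(a, b, cost)
    n, m = len(a), len(b)
    best, _ = _final_state(mats[0], mats[1], mats[2], n, m)
    steps = _traceback(a, b, mats)
    med = []
    col_a: list = []
    col_b: list = []
    for state, i, j in steps:
        if state == 0:
            ca, cb = int(a.cols[i - 1]), int(b.cols[j - 1])
            col_a.append(ca)
            col_b.append(cb)
            med.append(_median_column(ca, cb))
        elif state == 1:
            ca = int(a.cols[i - 1])
            col_a.append(ca)
            col_b.append(None)
            med.append(ca | GAP_BIT)
        else:
            cb = int(b.cols[j - 1])
            col_a.append(None)
            col_b.append(cb)
            med.append(cb | GAP_BIT)
    counters.medians += 1
    return AlignmentResult(
        cost=int(best),
        median=RAG(med),
        aligned_a=tuple(col_a),
        aligned_b=tuple(col_b),
    )


def distance(a: RAG, b: RAG, cost: CostModel) -> int:
    """Affine DO distance: ``align(a, b, cost).cost`` without the traceback."""
    mats = _dp(a, b, cost)
    best, _ = _final_state(mats[0], mats[1], mats[2], len(a), len(b))
    return int(best)


def merge_union(a: RAG, b: RAG, cost: CostModel) -> RAG:
    """Union of two RAGs: align them and emit, per aligned position, the set
    union of the ``a`` column, ``b`` column, and median column present there,
    adding the indel symbol wherever ``a`` or ``b`` contributed a gap so that
    skipped inputs remain recoverable.

    Every sequence contained in ``a``, ``b``, or the median is contained in
    the result, and the number of emitted columns is at most ``|a| + |b|``.
    """
    if len(a) == 0 and len(b) == 0:
        return EMPTY_RAG
    res = align(a, b, cost)
    out = []
    for ca, cb, cm in zip(res.aligned_a, res.aligned_b, res.median.cols):
        col = int(cm)
        if ca is not None:
            col |= ca
        else:
            col |= GAP_BIT
        if cb is not None:
            col |= cb
        else:
            col |= GAP_BIT
        out.append(col)
    counters.union_merge_steps += len(out)
    return RAG(out)


def contains(r: RAG, s: str) -> bool:
    """True iff plain sequence ``s`` (over ACGT) is contained in ``r``: it can
    be spelled by choosing one symbol per column in order, deleting chosen
    indels."""
    try:
        want = [IUPAC_MASKS[ch] for ch in s.upper()]
    except KeyError as exc:
        raise ValueError(f"not a DNA base: {exc.args[0]!r}") from None
    for w in want:
        if w not in (A_BIT, C_BIT, G_BIT, T_BIT):
            raise ValueError("contains() expects an unambiguous ACGT sequence")
    n, m = len(r), len(want)
    # reachable[j] = can spell s[j:] from the remaining columns
    reachable = np.zeros(m + 1, dtype=bool)
    reachable[m] = True
    for i in range(n - 1, -1, -1):
        col = int(r.cols[i])
        new = np.zeros(m + 1, dtype=bool)
        if col & GAP_BIT:
            new |= reachable  # choose the indel, skip this column
        for j in range(m):
            if reachable[j + 1] and (col & want[j]):
                new[j] = True
        reachable = new
    return bool(reachable[0])
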