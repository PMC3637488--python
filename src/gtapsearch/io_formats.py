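"""File formats and run configuration.

FASTA in (unaligned IUPAC DNA, no gap characters), Newick in/out (trees are
unrooted internally; output is rooted canonically on the lexicographically
smallest leaf so files are diffable), and a flat key/value YAML run
configuration that fails fast on unknown keys.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import dendropy
import yaml

from .rag_align import IUPAC_MASKS, CostModel
from .tree_core import UnrootedTree, _vertex_ids

__all__ = [
    "SequenceRecord", "FastaFormatError", "read_fasta", "write_fasta",
    "read_newick", "write_newick", "RunConfig", "parse_config",
]


class FastaFormatError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class SequenceRecord:
    """An unaligned DNA sequence: a nonempty id and IUPAC residues
    (uppercase, no gap characters; may be empty)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        for ch in self.residues:
            if ch not in IUPAC_MASKS:
                raise ValueError(
                    f"record {self.id!r}: not an IUPAC DNA code: {ch!r}"
                )


def read_fasta(path) -> List[SequenceRecord]:
    """Read a FASTA file into records, order preserved, residues uppercased.

    Raises :class:`FastaFormatError` (naming the line) for malformed headers
    or illegal characters, and ``ValueError`` for duplicate ids.
    """
    records: List[SequenceRecord] = []
    seen: Set[str] = set()
    header: Optional[str] = None
    chunks: List[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        if header in seen:
            raise ValueError(f"duplicate sequence id {header!r}")
        seen.add(header)
        records.append(SequenceRecord(header, "".join(chunks)))
        header, chunks = None, []

    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(i)
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise FastaFormatError("empty FASTA header", i)
        else:
            if header is None:
                raise FastaFormatError(
                    "sequence data before any '>' header", i)
            up = line.upper()
            for ch in up:
                if ch not in IUPAC_MASKS:
                    raise FastaFormatError(
                        f"illegal character {ch!r} in sequence {header!r}", i)
            chunks.append(up)
    flush(len(lines) + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    def emit(fh) -> None:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i:i + 70] + "\n")
            if not rec.residues:
                fh.write("\n")

    if hasattr(path, "write"):
        emit(path)
    else:
        with open(path, "w") as fh:
            emit(fh)


def read_newick(text: str, leaf_ids: Optional[Set[str]] = None) -> UnrootedTree:
    """Parse a Newick string into an unrooted binary tree.

    A rooted binary input is unrooted by merging the root's two edges.
    Polytomies are rejected; if ``leaf_ids`` is given the leaf set must
    match it exactly.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from None

    adj: Dict[int, List[int]] = {}
    leaf_label: Dict[int, str] = {}
    node_id: Dict[int, int] = {}

    def vid(node) -> int:
        key = id(node)
        if key not in node_id:
            node_id[key] = next(_vertex_ids)
            adj[node_id[key]] = []
        return node_id[key]

    root = dtree.seed_node
    for node in dtree.preorder_node_iter():
        kids = node.child_nodes()
        if node is root:
            if len(kids) == 0:
                pass
            elif len(kids) not in (2, 3):
                if len(kids) == 1:
                    raise ValueError("degree-1 root is not supported")
                raise ValueError(
                    f"polytomy at root (degree {len(kids)})")
        elif kids and len(kids) != 2:
            raise ValueError(
                f"polytomy: internal node with {len(kids)} children")
        if not kids:
            if node.taxon is None or not node.taxon.label:
                raise ValueError("unlabeled leaf in Newick input")
            leaf_label[vid(node)] = node.taxon.label
        for child in kids:
            u, v = vid(node), vid(child)
            adj[u].append(v)
            adj[v].append(u)

    if len(leaf_label) != len(set(leaf_label.values())):
        raise ValueError("duplicate leaf labels in Newick input")
    if leaf_ids is not None and set(leaf_label.values()) != set(leaf_ids):
        raise ValueError(
            f"leaf set mismatch: tree has {sorted(leaf_label.values())}, "
            f"expected {sorted(leaf_ids)}")

    # A rooted binary input has a degree-2 root: merge its two edges.
    rv = node_id[id(root)]
    if len(adj[rv]) == 2 and rv not in leaf_label:
        a, b = adj[rv]
        adj[a] = [b if z == rv else z for z in adj[a]]
        adj[b] = [a if z == rv else z for z in adj[b]]
        del adj[rv]
    return UnrootedTree(adj, leaf_label)


def write_newick(tree: UnrootedTree) -> str:
    """Canonical Newick output; re-parses to an isomorphic tree."""
    return tree.canonical_newick()


_CONFIG_KEYS = {
    # cost model
    "substitution": int, "indel": int, "gap_opening": int,
    # build
    "build": str, "lookahead": int, "union_prune": bool,
    # search
    "neighborhood": str, "break_order": str, "join_order": str,
    "union_threshold": float, "mode": str,
    "sector_diameter": object, "reroot_diameter": object,
    "annealing_temperature": float, "annealing_coefficient": float,
    # run
    "seed": int,
    # simulation
    "sim_leaves": int, "sim_branch_length": object, "sim_max_gap": int,
    "sim_root_length": int, "sim_substitution_rate": float,
    "sim_indel_rate": float, "sim_power_exponent": float,
}

_BUILDERS = {"ras", "mst", "nj"}
_NEIGHBORHOODS = {"tbr", "spr"}
_ORDERS_BREAK = {"random", "length"}
_ORDERS_JOIN = {"random", "union"}
_MODES = {"e", "ne"}


@dataclass
class RunConfig:
    """A complete run configuration: cost model, builder, search policy
    parameters, seed, and optional simulation settings."""

    cost: CostModel
    build: Dict[str, object] = field(default_factory=dict)
    search: Dict[str, object] = field(default_factory=dict)
    seed: int = 0
    simulation: Optional[Dict[str, object]] = None


def parse_config(text: str) -> RunConfig:
    """Parse a flat key/value YAML document; unknown keys are errors."""
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ValueError("config must be a flat key/value document")
    unknown = set(doc) - set(_CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    cost = CostModel(
        substitution=int(doc.get("substitution", 1)),
        indel=int(doc.get("indel", 1)),
        gap_opening=int(doc.get("gap_opening", 0)),
    )
    build: Dict[str, object] = {}
    if "build" in doc:
        name = str(doc["build"]).lower()
        if name not in _BUILDERS:
            raise ValueError(f"unknown builder {name!r}; "
                             f"choose from {sorted(_BUILDERS)}")
        build["method"] = name
    if "lookahead" in doc:
        k = int(doc["lookahead"])
        if k < 1:
            raise ValueError("lookahead must be >= 1")
        build["lookahead"] = k
    if "union_prune" in doc:
        build["union_prune"] = bool(doc["union_prune"])

    search: Dict[str, object] = {}
    for key, allowed in (
        ("neighborhood", _NEIGHBORHOODS), ("break_order", _ORDERS_BREAK),
        ("join_order", _ORDERS_JOIN), ("mode", _MODES),
    ):
        if key in doc:
            val = str(doc[key]).lower()
            if val not in allowed:
                raise ValueError(
                    f"unknown {key} {val!r}; choose from {sorted(allowed)}")
            search[key] = val
    for key in ("union_threshold", "sector_diameter", "reroot_diameter",
                "annealing_temperature", "annealing_coefficient"):
        if key in doc:
            search[key] = doc[key]

    sim = None
    sim_keys = {k: v for k, v in doc.items() if k.startswith("sim_")}
    if sim_keys:
        sim = {k[len("sim_"):]: v for k, v in sim_keys.items()}
    return RunConfig(cost=cost, build=build, search=search,
                     seed=int(doc.get("seed", 0)), simulation=sim)
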