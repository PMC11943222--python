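"""Neighbor-joining phylogeny of amino-acid domains with bootstrap support.

Consumes an existing amino-acid alignment (e.g. reverse-transcriptase
domains extracted from TE loci), computes pairwise distances under a
p-distance, Poisson correction, or a JTT-motivated closed-form correction,
builds the Saitou–Nei neighbor-joining topology with deterministic
tie-breaking, and attaches bootstrap supports by column resampling.
Trees serialize to Newick with integer supports as internal labels.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, Phylo

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "Node",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap",
    "write_newick",
    "parse_newick",
]


class SaturationError(ValueError):
    """Observed divergence outside the distance model's domain."""


@dataclass
class Alignment:
    """Equal-length aligned amino-acid sequences with '-' gaps."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        return Alignment(list(self.ids), rows)

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        aln = AlignIO.read(path, "fasta")
        return cls([rec.id for rec in aln], [str(rec.seq) for rec in aln])

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


@dataclass
class DistanceMatrix:
    """Symmetric distances with a zero diagonal."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        self.values = v


@dataclass
class Node:
    """Tree node; the root of an unrooted NJ tree is a trifurcation."""

    name: str | None = None
    branch_length: float = 0.0
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


def pairwise_distance(aln: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances with pairwise gap deletion.

    Models: ``p`` (mismatch fraction), ``poisson`` (d = -ln(1-p)) and
    ``jtt_like`` (d = -ln(1 - p - 0.2 p^2), a closed-form correction with
    curvature matched to empirical amino-acid models; no rate scaling is
    applied).  Pairs beyond the model's domain raise SaturationError.
    """
    if aln.n_seqs < 2:
        raise ValueError("need >=2 sequences")
    if model not in {"p", "poisson", "jtt_like"}:
        raise ValueError(f"unknown model {model!r}")
    n = aln.n_seqs
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.rows[i], aln.rows[j]
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not pairs:
                raise SaturationError(
                    f"no shared ungapped columns for {aln.ids[i]}/{aln.ids[j]}")
            p = sum(x != y for x, y in pairs) / len(pairs)
            if model == "p":
                dist = p
            elif model == "poisson":
                arg = 1 - p
                if arg <= 0:
                    raise SaturationError(
                        f"saturated pair {aln.ids[i]}/{aln.ids[j]} (p={p:.3f})")
                dist = -np.log(arg)
            else:
                arg = 1 - p - 0.2 * p * p
                if arg <= 0:
                    raise SaturationError(
                        f"saturated pair {aln.ids[i]}/{aln.ids[j]} (p={p:.3f})")
                dist = -np.log(arg)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(list(aln.ids), d)


def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    At each step the pair minimizing the Q criterion is joined; exact ties
    break to the lexicographically smallest (label_i, label_j) pair.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch.  Returns the unrooted tree as a trifurcating root.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >=3 taxa")
    nodes = [Node(name=t) for t in dm.taxa]
    # label used only for deterministic tie-breaking
    labels = list(dm.taxa)
    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        ni, nj = nodes[i], nodes[j]
        ni.branch_length, nj.branch_length = li, lj
        parent = Node(children=[ni, nj])
        # grow matrix with the new node's distances
        D = np.pad(D, ((0, 1), (0, 1)))
        new = D.shape[0] - 1
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        labels.append(min(labels[i], labels[j]))
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    # three-point formulas for the final star
    bi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    bj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    bk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    order = sorted(zip((labels[i], labels[j], labels[k]), (i, j, k),
                       (bi, bj, bk)))
    root = Node()
    for _, idx, bl in order:
        nodes[idx].branch_length = max(bl, 0.0)
        root.children.append(nodes[idx])
    return root


def _bipartitions(tree: Node) -> set[frozenset]:
    """Non-trivial bipartitions, each canonicalized to the side not
    containing the alphabetically first leaf."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    parts = set()

    def walk(node: Node):
        names = frozenset(node.leaf_names())
        if 1 < len(names) < len(all_leaves) - 1:
            side = names if ref not in names else all_leaves - names
            parts.add(side)
        for c in node.children:
            walk(c)

    for c in tree.children:
        walk(c)
    return parts


def bootstrap(aln: Alignment, n_reps: int = 1000, model: str = "poisson",
              seed: int = 0) -> Node:
    """NJ point-estimate tree with column-resampling bootstrap supports.

    Supports are the percentage of replicate trees containing each
    internal bipartition of the point-estimate tree, rounded to integers.
    Replicates whose resampled distances saturate are skipped (counted as
    not supporting).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = neighbor_joining(pairwise_distance(aln, model))
    target = {bp: 0 for bp in _bipartitions(point)}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep_aln = aln.resample_columns(rng)
        try:
            rep_tree = neighbor_joining(pairwise_distance(rep_aln, model))
        except SaturationError:
            continue
        rep_parts = _bipartitions(rep_tree)
        for bp in target:
            if bp in rep_parts:
                target[bp] += 1

    def attach(node: Node):
        names = frozenset(node.leaf_names())
        all_names = frozenset(point.leaf_names())
        ref = min(all_names)
        if not node.is_leaf():
            side = names if ref not in names else all_names - names
            if side in target:
                node.support = round(100 * target[side] / n_reps)
        for c in node.children:
            attach(c)

    for c in point.children:
        attach(c)
    return point


def _escape(label: str) -> str:
    if any(ch in label for ch in "(),:;'\" \t[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Node) -> str:
    """Serialize with branch lengths and integer supports as inner labels."""
    if tree is None or (tree.is_leaf() and tree.name is None):
        raise ValueError("empty tree")

    def fmt(node: Node) -> str:
        if node.is_leaf():
            return f"{_escape(node.name)}:{node.branch_length:g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else str(int(node.support))
        return f"({inner}){label}:{node.branch_length:g}"

    inner = ",".join(fmt(c) for c in tree.children)
    label = "" if tree.support is None else str(int(tree.support))
    return f"({inner}){label};"


def parse_newick(text: str) -> Node:
    """Parse a Newick string back into the module's Node tree."""
    clade = Phylo.read(_io.StringIO(text), "newick").root

    def convert(cl) -> Node:
        node = Node(name=cl.name,
                    branch_length=float(cl.branch_length or 0.0))
        if cl.clades:
            conf = cl.confidence
            if conf is None and cl.name and cl.name.isdigit():
                conf = int(cl.name)
                node.name = None
            node.support = None if conf is None else int(conf)
            node.children = [convert(c) for c in cl.clades]
        return node

    return convert(clade)
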