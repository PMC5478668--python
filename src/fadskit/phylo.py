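"""Distance-based protein phylogenetics: p/Poisson distances, neighbor
joining, column bootstrap, and Newick I/O.

The estimator chain mirrors the classical distance workflow for protein
alignments: pairwise distances under pairwise gap deletion (uncorrected
p-distance or its Poisson correction ``-ln(1 - p)``), Saitou–Nei neighbor
joining with deterministic tie-breaking, and non-parametric bootstrap over
alignment columns with bipartition supports mapped back onto the
point-estimate tree as integer percentages.

All components are implemented here rather than delegated, so that every
numerical choice (tie-breaks, negative-limb handling, the replicate RNG
contract) is explicit and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
from Bio import SeqIO

__all__ = [
    "ProteinAlignment",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "NoComparableColumnsError",
    "SaturationError",
    "NewickParseError",
    "pairwise_distance",
    "neighbor_joining",
    "bootstrap_support",
    "to_newick",
    "parse_newick",
    "robinson_foulds",
    "read_phylip_dm",
    "write_phylip_dm",
]

_GAP = ord("-")


class NoComparableColumnsError(ValueError):
    """A sequence pair shares no ungapped column."""


class SaturationError(ValueError):
    """p = 1 for a pair: the Poisson correction -ln(1-p) diverges."""


class NewickParseError(ValueError):
    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


# ---------------------------------------------------------------------------
# Alignment


class ProteinAlignment:
    """An aligned set of gapped protein sequences with unique ids."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]) -> None:
        if len(ids) != len(rows):
            raise ValueError("ids and rows differ in count")
        if len(set(ids)) != len(ids):
            raise ValueError("alignment ids must be unique")
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]
        self.length = lengths.pop() if lengths else 0
        self._matrix = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.rows), self.length) if self.rows else np.zeros((0, 0), np.uint8)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def matrix(self) -> np.ndarray:
        """(n_taxa, n_columns) byte matrix view of the alignment."""
        return self._matrix

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "ProteinAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(v)):
            raise ValueError("distances must be finite")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        if np.any(np.abs(np.diagonal(v)) > 0):
            raise ValueError("diagonal must be exactly zero")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("matrix must be symmetric (tolerance 1e-12)")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def _distances_from_matrix(
    mat: np.ndarray, labels: Sequence[str], model: str
) -> DistanceMatrix:
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    n = mat.shape[0]
    valid = mat != _GAP
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = valid[i] & valid[j]
            ncomp = int(mask.sum())
            if ncomp == 0:
                raise NoComparableColumnsError(
                    f"pair ({labels[i]}, {labels[j]}) shares no ungapped column"
                )
            p = float(np.count_nonzero(mat[i, mask] != mat[j, mask])) / ncomp
            if model == "poisson":
                if p >= 1.0:
                    raise SaturationError(
                        f"pair ({labels[i]}, {labels[j]}) is saturated (p = 1)"
                    )
                d = -math.log1p(-p)
            else:
                d = p
            out[i, j] = out[j, i] = d
    return DistanceMatrix(list(labels), out)


def pairwise_distance(aln: ProteinAlignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise protein distances under pairwise gap deletion.

    ``model="p"`` is the raw mismatch proportion over compared columns;
    ``model="poisson"`` applies the multiple-hit correction ``-ln(1 - p)``.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    return _distances_from_matrix(aln.matrix, aln.ids, model)


# ---------------------------------------------------------------------------
# Trees


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[int] = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class PhyloTree:
    """An unrooted tree stored rooted at a basal multifurcation."""

    root: TreeNode
    skipped_replicates: int = 0

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def bipartitions(self) -> dict[frozenset, Optional[int]]:
        """Internal-edge bipartitions mapped to their support (or None).

        Each bipartition is identified by the leaf-name side *not*
        containing the lexicographically smallest leaf, so the encoding is
        independent of the rooting.
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        out: dict[frozenset, Optional[int]] = {}

        def clade(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            got = frozenset().union(*(clade(c) for c in node.children))
            if node is not self.root and 2 <= len(got) <= len(all_leaves) - 2:
                side = all_leaves - got if ref in got else got
                out[side] = node.support
            return got

        clade(self.root)
        return out


def _nj_limbs(d_ij: float, r_i: float, r_j: float, m: int) -> tuple[float, float]:
    li = 0.5 * d_ij + (r_i - r_j) / (2.0 * (m - 2))
    lj = d_ij - li
    # clamp a negative limb to zero, moving the deficit onto its sister so
    # the pair still spans d_ij
    if li < 0.0:
        li, lj = 0.0, d_ij
    elif lj < 0.0:
        li, lj = d_ij, 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    At each step the pair minimising
    ``Q(i,j) = (m-2) d(i,j) - R_i - R_j`` is joined; ties break on the
    lowest (row, column) pair in current label order, making runs
    bit-reproducible.  Negative limb estimates are clamped to zero with the
    deficit moved to the sister limb.  The result is unrooted (the root is
    the final trifurcation, or the join of three remaining subtrees).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes = [TreeNode(name=lbl) for lbl in dm.labels]
    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        rowsums = sub.sum(axis=1)
        q = (m - 2) * sub - rowsums[:, None] - rowsums[None, :]
        iu = np.triu_indices(m, 1)
        # np.argmin takes the first minimum in row-major upper-triangle
        # order, i.e. the lowest (row, column) pair on ties
        k_best = int(np.argmin(q[iu]))
        a, b = int(iu[0][k_best]), int(iu[1][k_best])
        i, j = active[a], active[b]
        li, lj = _nj_limbs(sub[a, b], rowsums[a], rowsums[b], m)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for c in range(m):
            k = active[c]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    d_ij, d_ik, d_jk = D[i, j], D[i, k], D[j, k]
    li = max(0.0, 0.5 * (d_ij + d_ik - d_jk))
    lj = max(0.0, 0.5 * (d_ij + d_jk - d_ik))
    lk = max(0.0, 0.5 * (d_ik + d_jk - d_ij))
    for node, limb in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = limb
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root)


def robinson_foulds(t1: PhyloTree, t2: PhyloTree) -> int:
    """Symmetric bipartition-set difference between two unrooted trees."""
    if set(t1.leaf_names()) != set(t2.leaf_names()):
        raise ValueError("trees must share a leaf set")
    b1 = set(t1.bipartitions())
    b2 = set(t2.bipartitions())
    return len(b1 ^ b2)


def tree_path_distances(tree: PhyloTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length (additive) distances of a tree."""
    labels = tree.leaf_names()
    index = {name: k for k, name in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))

    def below(node: TreeNode) -> dict[int, float]:
        if node.is_leaf:
            return {index[node.name]: 0.0}
        per_child = []
        for child in node.children:
            depths = {k: d + (child.length or 0.0) for k, d in below(child).items()}
            per_child.append(depths)
        for x in range(len(per_child)):
            for y in range(x + 1, len(per_child)):
                for ka, da in per_child[x].items():
                    for kb, db in per_child[y].items():
                        out[ka, kb] = out[kb, ka] = da + db
        merged: dict[int, float] = {}
        for depths in per_child:
            merged.update(depths)
        return merged

    below(tree.root)
    return DistanceMatrix(labels, out)


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    aln: ProteinAlignment,
    model: str = "poisson",
    iterations: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ point tree with column-bootstrap supports on internal edges.

    Each replicate resamples alignment columns with replacement (same
    length), recomputes distances and NJ, and contributes its bipartitions.
    Support = percentage (integer, half-up at .5) of usable replicates
    containing the bipartition.  A replicate whose resampled columns leave
    some pair with nothing to compare is skipped and counted in
    ``skipped_replicates``.  A single seeded generator drives all
    replicates in order, so results depend only on (alignment, model,
    iterations, seed).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    tree = neighbor_joining(pairwise_distance(aln, model))
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    mat = aln.matrix
    length = aln.length
    skipped = 0
    for _ in range(iterations):
        cols = rng.integers(0, length, size=length)
        try:
            rep_dm = _distances_from_matrix(mat[:, cols], aln.ids, model)
        except (NoComparableColumnsError, SaturationError):
            skipped += 1
            continue
        rep_bips = set(neighbor_joining(rep_dm).bipartitions())
        for bp in counts:
            if bp in rep_bips:
                counts[bp] += 1
    usable = iterations - skipped
    if usable == 0:
        raise RuntimeError("all bootstrap replicates were skipped")

    all_leaves = frozenset(aln.ids)
    ref = min(all_leaves)

    def annotate(node: TreeNode) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        got = frozenset().union(*(annotate(c) for c in node.children))
        if node is not tree.root and 2 <= len(got) <= len(all_leaves) - 2:
            side = all_leaves - got if ref in got else got
            node.support = int(
                math.floor(100.0 * counts[side] / usable + 0.5)
            )
        return got

    annotate(tree.root)
    tree.skipped_replicates = skipped
    return tree


# ---------------------------------------------------------------------------
# Newick I/O

_NEWICK_SPECIALS = set("(),:;'\"[]\t\n ")


def _write_node(node: TreeNode, is_root: bool) -> str:
    if node.is_leaf:
        if node.name is None:
            raise ValueError("leaf without a name")
        if set(node.name) & _NEWICK_SPECIALS:
            raise ValueError(f"leaf name {node.name!r} needs quoting; rename it")
        text = node.name
    else:
        text = "(" + ",".join(_write_node(c, False) for c in node.children) + ")"
        if node.support is not None:
            text += str(int(node.support))
        elif node.name:
            text += node.name
    if not is_root and node.length is not None:
        text += f":{node.length:.12g}"
    return text


def to_newick(tree: PhyloTree) -> str:
    """Newick string with branch lengths and integer supports as internal labels."""
    return _write_node(tree.root, True) + ";"


def parse_newick(text: str) -> PhyloTree:
    """Parse standard Newick; numeric internal labels are read as supports."""
    pos = 0

    def error(msg: str) -> NewickParseError:
        return NewickParseError(msg, pos)

    def skip_ws() -> None:
        nonlocal pos
        while pos < len(text) and text[pos].isspace():
            pos += 1

    def parse_label() -> str:
        nonlocal pos
        start = pos
        while pos < len(text) and text[pos] not in "(),:;":
            pos += 1
        return text[start:pos].strip()

    def parse_node() -> TreeNode:
        nonlocal pos
        skip_ws()
        node = TreeNode()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                skip_ws()
                if pos >= len(text):
                    raise error("unterminated subtree")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise error(f"expected ',' or ')', found {text[pos]!r}")
            label = parse_label()
            if label:
                try:
                    node.support = int(round(float(label)))
                except ValueError:
                    node.name = label
        else:
            label = parse_label()
            if not label:
                raise error("expected a leaf label")
            node.name = label
        skip_ws()
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and (text[pos] not in "(),:;"):
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                raise error(f"invalid branch length {text[start:pos]!r}")
        return node

    root = parse_node()
    skip_ws()
    if pos >= len(text) or text[pos] != ";":
        raise error("expected terminating ';'")
    if root.is_leaf:
        raise error("tree must contain at least one internal node")
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices


def read_phylip_dm(path: Union[str, Path]) -> DistanceMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(labels, np.array(rows))


def write_phylip_dm(dm: DistanceMatrix, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for lbl, row in zip(dm.labels, dm.values):
            fh.write(lbl + "  " + "  ".join(f"{x:.9f}" for x in row) + "\n")


def reroot_at_leaf(tree: PhyloTree, leaf_name: str) -> PhyloTree:
    """Re-root so that ``leaf_name`` is the outgroup child of a 2-way root.

    The outgroup's pendant branch is split in half around the new root.
    Supports stay attached to the clades they annotate.
    """
    parent: dict[int, tuple[Optional[TreeNode], TreeNode]] = {}
    target = None
    for node in tree.root.walk():
        for child in node.children:
            parent[id(child)] = (node, child)
        if node.is_leaf and node.name == leaf_name:
            target = node
    if target is None:
        raise ValueError(f"leaf {leaf_name!r} not in tree")

    # walk from the target's parent back to the old root, reversing edges
    def detach(node: TreeNode, child: TreeNode) -> None:
        node.children = [c for c in node.children if c is not child]

    half = (target.length or 0.0) / 2.0
    old_parent = parent[id(target)][0]
    detach(old_parent, target)

    new_root = TreeNode()
    target.length = half
    new_root.children = [target]

    # reverse the path old_parent -> ... -> old root
    node = old_parent
    carried_length = half
    prev = None
    while node is not None:
        up = parent.get(id(node))
        up_node = up[0] if up else None
        if up_node is not None:
            detach(up_node, node)
        length_to_parent = node.length
        node.length = carried_length
        if prev is None:
            new_root.children.append(node)
        else:
            node.children = [c for c in node.children]
            prev.children.append(node)
        carried_length = length_to_parent
        prev = node
        node = up_node
    # the old root may now be an internal node of degree 2 inside prev's
    # children; collapse degree-2 pass-through nodes
    _collapse_unary(new_root)
    return PhyloTree(new_root)


def _collapse_unary(node: TreeNode) -> None:
    for child in list(node.children):
        _collapse_unary(child)
        if len(child.children) == 1:
            (grand,) = child.children
            grand.length = (grand.length or 0.0) + (child.length or 0.0)
            node.children[node.children.index(child)] = grand
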