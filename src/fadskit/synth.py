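"""Ground-truth generators and packaged reference tables.

Two simulators feed the pipeline stages with inputs whose true answers are
known by construction:

* :func:`simulate_assay` emulates a co-transformant yeast culture fed an
  exogenous PUFA: substrate area flows along a pathway route with known
  per-step conversion fractions, and each final peak area receives
  multiplicative lognormal noise (chromatographic areas are positive with
  roughly proportional error).  β-oxidation never appears in simulated
  routes: the yeast system lacks the peroxisomal step, so 24:6n-3
  accumulates rather than converting onward.

* :func:`simulate_family` evolves a protein family along a random
  bifurcating tree, embedding the Δ4-signature region in the root; a chosen
  clade keeps the Y/N anchors intact while all other taxa receive a forced
  disruptive anchor substitution, giving an exact intact/disrupted truth
  table.

:func:`load_fixture` exposes the packaged reference tables: the 15-enzyme
C24 Δ6-activity table with its printed normalisation ratios, the 12-row
substrate-conversion table for the two newly characterised Δ4 enzymes, and
the default pathway graph.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np

from .fa import FattyAcid, PathwayGraph, default_pathway_graph, parse_fa_shorthand
from .motifscan import AMINO_ACIDS, DEFAULT_QUERY, WILDCARD, MotifQuery
from .phylo import PhyloTree, TreeNode, to_newick
from .quant import (
    ND,
    AssayRecord,
    ConversionResult,
    PeakTable,
)
from .fa import classify_conversion

__all__ = [
    "AssaySimSpec",
    "FamilySimSpec",
    "simulate_assay",
    "simulate_family",
    "random_tree",
    "suggested_max_mismatches",
    "load_fixture",
    "Table1Row",
    "Table2Row",
]


# ---------------------------------------------------------------------------
# Assay simulation


@dataclass
class AssaySimSpec:
    """Simulation spec for one yeast assay culture.

    ``true_step_fractions`` lists ``((substrate_label, product_label),
    fraction)`` pairs in route order; each step moves ``fraction`` of the
    area arriving at its substrate onward to the product.  ``noise_cv`` is
    the coefficient of variation of the per-peak multiplicative lognormal
    noise.
    """

    exogenous_substrate: FattyAcid
    true_step_fractions: Sequence[tuple[tuple[str, str], float]]
    total_substrate_area: float = 1e6
    noise_cv: float = 0.05
    seed: int = 0

    @classmethod
    def c24_assay(
        cls,
        elongation_fraction: float,
        d6_fraction: float,
        **kwargs,
    ) -> "AssaySimSpec":
        """The C24 assay design: 22:5n-3 --elongation--> 24:5n-3 --Δ6--> 24:6n-3."""
        return cls(
            exogenous_substrate=parse_fa_shorthand("22:5n-3"),
            true_step_fractions=[
                (("22:5n-3", "24:5n-3"), elongation_fraction),
                (("24:5n-3", "24:6n-3"), d6_fraction),
            ],
            **kwargs,
        )


def simulate_assay(
    spec: AssaySimSpec,
    graph: Optional[PathwayGraph] = None,
    assay_id: str = "sim",
) -> tuple[PeakTable, list[ConversionResult]]:
    """Simulate one peak table plus its noiseless per-step ground truth.

    Area allocation is sequential along the route; with zero noise the
    recorded peak areas reproduce each true step conversion exactly
    (conversion of a step equals 100 x its fraction by construction).
    """
    graph = graph if graph is not None else default_pathway_graph()
    rng = np.random.default_rng(spec.seed)
    if not 0 <= spec.noise_cv:
        raise ValueError("noise_cv must be >= 0")
    if spec.total_substrate_area <= 0:
        raise ValueError("total_substrate_area must be positive")

    # validate the route is a path in the graph starting at the substrate
    current = spec.exogenous_substrate
    steps: list[tuple[FattyAcid, FattyAcid, float]] = []
    for (sub_label, prod_label), fraction in spec.true_step_fractions:
        sub = parse_fa_shorthand(sub_label)
        prod = parse_fa_shorthand(prod_label)
        if sub != current:
            raise ValueError(
                f"route edge {sub_label}->{prod_label} does not continue the "
                f"path (expected substrate {current.label})"
            )
        if not graph.has_edge(sub, prod):
            raise ValueError(f"edge {sub_label}->{prod_label} absent from graph")
        if not 0.0 <= fraction < 1.0:
            raise ValueError(f"step fraction must be in [0, 1), got {fraction}")
        steps.append((sub, prod, fraction))
        current = prod

    # sequential allocation: node k retains what the next step does not take
    areas: dict[str, float] = {}
    truths: list[ConversionResult] = []
    incoming = spec.total_substrate_area
    for sub, prod, fraction in steps:
        moved = fraction * incoming
        areas[sub.label] = incoming - moved
        truths.append(
            ConversionResult(
                sub, prod, classify_conversion(sub, prod), 100.0 * fraction
            )
        )
        incoming = moved
    areas[current.label] = incoming

    # drop product peaks that were never formed; keep the exogenous substrate
    areas = {
        lbl: a
        for lbl, a in areas.items()
        if a > 0 or lbl == spec.exogenous_substrate.label
    }

    if spec.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2))
        mu = -0.5 * sigma**2  # unit-mean lognormal
        for lbl in list(areas):
            areas[lbl] *= float(rng.lognormal(mean=mu, sigma=sigma))

    table = PeakTable(
        assay_id=assay_id,
        areas=areas,
        exogenous_substrate=spec.exogenous_substrate,
    )
    return table, truths


# ---------------------------------------------------------------------------
# Family simulation


@dataclass
class FamilySimSpec:
    """Simulation spec for a protein family evolved along a random tree.

    ``tree_height`` is the root-to-leaf depth in expected substitutions per
    site when ``substitution_rate`` is 1.  ``signature_clade_fraction`` of
    the taxa (rounded to the nearest count) form a clade whose Y/N anchors
    stay intact; every other taxon receives a forced disruptive anchor
    substitution.
    """

    n_taxa: int = 20
    tree_height: float = 0.15
    substitution_rate: float = 1.0
    root_sequence_length: int = 350
    signature: MotifQuery = field(default_factory=lambda: DEFAULT_QUERY)
    signature_clade_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.signature_clade_fraction <= 1.0:
            raise ValueError("signature_clade_fraction must be in [0, 1]")
        if self.root_sequence_length < self.signature.length:
            raise ValueError("root sequence shorter than the signature")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")


def _join_random(
    nodes: list[TreeNode], rng: np.random.Generator, mean_branch: float,
    min_branch: float,
) -> TreeNode:
    """Coalescent-style random joins with exponential branch lengths."""
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(int(j))
        left = nodes.pop(int(i))
        for child in (left, right):
            child.length = min_branch + float(rng.exponential(mean_branch))
        nodes.append(TreeNode(children=[left, right]))
    return nodes[0]


def random_tree(
    n_taxa: int,
    rng: Union[int, np.random.Generator],
    mean_branch: float = 0.5,
    min_branch: float = 0.05,
    prefix: str = "T",
) -> PhyloTree:
    """Random bifurcating tree with strictly positive branch lengths.

    Leaves are named ``{prefix}01 .. {prefix}NN``.  With ``min_branch > 0``
    every internal edge is resolvable, so the leaf-to-leaf path distances
    are an additive metric whose unique tree is this one.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    width = max(2, len(str(n_taxa)))
    leaves = [TreeNode(name=f"{prefix}{k + 1:0{width}d}") for k in range(n_taxa)]
    root = _join_random(leaves, rng, mean_branch, min_branch)
    return PhyloTree(root)


def _scale_to_height(tree: PhyloTree, height: float) -> None:
    def depth(node: TreeNode) -> float:
        own = node.length or 0.0
        if node.is_leaf:
            return own
        return own + max(depth(c) for c in node.children)

    current = depth(tree.root)
    if current <= 0:
        return
    factor = height / current
    for node in tree.root.walk():
        if node.length is not None:
            node.length *= factor


def simulate_family(
    spec: FamilySimSpec,
) -> tuple[list[tuple[str, str]], dict[str, bool], str]:
    """Evolve a signature-bearing protein family with exact truth labels.

    Returns ``(records, truth, newick)``: FASTA-ready (id, sequence) pairs
    in tree leaf order, a per-taxon intact/disrupted truth table whose
    intact count equals ``round(fraction * n_taxa)`` exactly, and the true
    tree in Newick.  Anchor columns are shielded from random substitution;
    disruption happens only through the forced anchor edits applied to taxa
    outside the signature clade.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_taxa
    k = int(round(spec.signature_clade_fraction * n))
    width = max(2, len(str(n)))
    names = [f"T{idx + 1:0{width}d}" for idx in range(n)]
    intact_names = set(names[:k])

    # build the tree so the intact taxa form a genuine clade (when 0 < k < n)
    mean_branch, min_branch = 0.5, 0.05
    leaf_nodes = {nm: TreeNode(name=nm) for nm in names}
    if 0 < k < n:
        clade_a = _join_random(
            [leaf_nodes[nm] for nm in names[:k]], rng, mean_branch, min_branch
        )
        clade_b = _join_random(
            [leaf_nodes[nm] for nm in names[k:]], rng, mean_branch, min_branch
        )
        for child in (clade_a, clade_b):
            child.length = min_branch + float(rng.exponential(mean_branch))
        root = TreeNode(children=[clade_a, clade_b])
    else:
        root = _join_random(list(leaf_nodes.values()), rng, mean_branch, min_branch)
    tree = PhyloTree(root)
    _scale_to_height(tree, spec.tree_height)

    # root sequence with the signature embedded at a random recorded offset
    L = spec.root_sequence_length
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    root_seq = aa[rng.integers(0, len(aa), size=L)].copy()
    offset = int(rng.integers(0, L - spec.signature.length + 1))
    for i, residue in enumerate(spec.signature.sequence):
        if residue == WILDCARD:
            residue = AMINO_ACIDS[int(rng.integers(0, len(aa)))]
        root_seq[offset + i] = ord(residue)
    y_pos = offset + spec.signature.y_anchor
    n_pos = y_pos + 3
    protected = {y_pos, n_pos}

    sequences: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        seq = seq.copy()
        branch = node.length or 0.0
        n_sub = int(rng.poisson(spec.substitution_rate * branch * L))
        sites = rng.integers(0, L, size=n_sub)
        for site in sites:
            site = int(site)
            if site in protected:
                continue
            old = seq[site]
            choices = aa[aa != old]
            seq[site] = choices[int(rng.integers(0, len(choices)))]
        if node.is_leaf:
            sequences[node.name] = seq
        else:
            for child in node.children:
                evolve(child, seq)

    evolve(tree.root, root_seq)

    truth: dict[str, bool] = {}
    records: list[tuple[str, str]] = []
    for name in [leaf.name for leaf in tree.leaves()]:
        seq = sequences[name]
        if name not in intact_names:
            # disrupt the Y or N anchor with a residue that breaks the motif
            pos = y_pos if rng.random() < 0.5 else n_pos
            required = ord("Y") if pos == y_pos else ord("N")
            choices = aa[aa != required]
            seq[pos] = choices[int(rng.integers(0, len(choices)))]
        truth[name] = name in intact_names
        records.append((name, seq.tobytes().decode("ascii")))
    return records, truth, to_newick(tree)


def suggested_max_mismatches(spec: FamilySimSpec) -> int:
    """Mismatch ceiling adapted to the simulation's substitution load.

    The expected mismatch count of an intact taxon's signature window is
    roughly (scored non-anchor positions) x (root-to-leaf substitutions per
    site); the ceiling adds a four-sigma Poisson margin.
    """
    scored = spec.signature.n_scored - 2  # anchors are protected
    lam = scored * spec.substitution_rate * spec.tree_height
    return min(scored, int(math.ceil(lam + 4.0 * math.sqrt(max(lam, 1.0)))))


def two_clade_alignment(
    n_per_clade: int = 4,
    n_columns: int = 200,
    divergent_fraction: float = 0.5,
    taxon_noise: float = 0.03,
    seed: int = 0,
):
    """Protein alignment of two clades split by fixed-divergent columns.

    A ``divergent_fraction`` of columns carries one residue in clade A and a
    different one in clade B (fixed within each clade); the rest are shared.
    Each taxon additionally mutates a ``taxon_noise`` fraction of sites so
    within-clade distances are positive.  The central bipartition
    (A-taxa | B-taxa) is supported by every divergent column, so its
    bootstrap support should sit near 100%.
    """
    from .phylo import ProteinAlignment

    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    base = aa[rng.integers(0, len(aa), size=n_columns)]
    n_div = int(round(divergent_fraction * n_columns))
    other = base.copy()
    for col in range(n_div):
        choices = aa[aa != base[col]]
        other[col] = choices[int(rng.integers(0, len(choices)))]
    ids, rows = [], []
    for clade, proto in (("A", base), ("B", other)):
        for t in range(n_per_clade):
            seq = proto.copy()
            n_mut = rng.binomial(n_columns, taxon_noise)
            for site in rng.integers(0, n_columns, size=n_mut):
                site = int(site)
                choices = aa[aa != seq[site]]
                seq[site] = choices[int(rng.integers(0, len(choices)))]
            ids.append(f"{clade}{t + 1}")
            rows.append(seq.tobytes().decode("ascii"))
    return ProteinAlignment(ids, rows)


# ---------------------------------------------------------------------------
# Packaged fixtures


@dataclass(frozen=True)
class Table1Row:
    record: AssayRecord
    printed_ratio: float


@dataclass(frozen=True)
class Table2Row:
    species: str
    result: ConversionResult


def _read_data_tsv(name: str) -> list[dict[str, str]]:
    text = resources.files("fadskit.data").joinpath(name).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def _pct(token: str) -> Optional[float]:
    return ND if token == "ND" else float(token)


def load_fixture(name: str):
    """Load a packaged reference structure.

    ``"table1"`` -> list of :class:`Table1Row` (15 enzymes: C24 conversion
    columns, control identity, and the printed normalisation ratio);
    ``"table2"`` -> list of :class:`Table2Row` (12 substrate conversions of
    the two Δ4 enzymes); ``"fig1_graph"`` -> the default pathway graph.
    """
    if name == "table1":
        rows = []
        for rec in _read_data_tsv("table1.tsv"):
            control = parse_fa_shorthand(rec["control_label"])
            product = parse_fa_shorthand(rec["control_product"])
            rows.append(
                Table1Row(
                    record=AssayRecord(
                        desaturase_id=rec["desaturase_id"],
                        conv_24_4n6=_pct(rec["conv_24_4n6"]),
                        conv_24_5n3=_pct(rec["conv_24_5n3"]),
                        control_substrate=control,
                        control_product=product,
                        conv_control=_pct(rec["conv_control"]),
                    ),
                    printed_ratio=float(rec["printed_ratio"]),
                )
            )
        return rows
    if name == "table2":
        rows = []
        for rec in _read_data_tsv("table2.tsv"):
            sub = parse_fa_shorthand(rec["fa_substrate"])
            prod = parse_fa_shorthand(rec["fa_product"])
            rows.append(
                Table2Row(
                    species=rec["species"],
                    # ConversionResult re-derives the activity label and
                    # raises if the printed one is inconsistent with the pair
                    result=ConversionResult(
                        sub, prod, rec["activity"], _pct(rec["conversion"])
                    ),
                )
            )
        return rows
    if name == "fig1_graph":
        return default_pathway_graph()
    raise KeyError(f"unknown fixture {name!r}")
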