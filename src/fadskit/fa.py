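"""Fatty-acid shorthand parsing and the LC-PUFA biosynthesis network.

Polyunsaturated fatty acids are written in ``C:Dn-x`` shorthand: ``C``
acyl-chain carbons, ``D`` double bonds, and ``n-x`` (equivalently ω-x) the
position of the terminal double bond counted from the methyl end.  All PUFA
handled here are methylene-interrupted: successive double bonds are spaced
exactly three carbons apart, so the full set of carboxyl-referenced (Δ)
double-bond positions is determined by ``(C, D, x)`` alone.

The module also encodes the accepted teleost LC-PUFA biosynthesis network —
Δ6 and Δ8 routes to EPA/ARA, the elongation chain to C24, the Sprecher
terminus (Δ6 desaturation of 24:5n-3 followed by partial β-oxidation), and
the direct Δ4 desaturation of 22:5n-3 — and classifies any substrate/product
pair by the single enzymatic activity connecting them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Optional

__all__ = [
    "FattyAcid",
    "FAParseError",
    "FAValidationError",
    "ClassificationError",
    "parse_fa_shorthand",
    "delta_positions",
    "classify_conversion",
    "PathwayGraph",
    "default_pathway_graph",
    "ELONGATION",
    "BETA_OXIDATION",
    "NOT_SINGLE_STEP",
]

ELONGATION = "elongation"
BETA_OXIDATION = "beta-oxidation"
NOT_SINGLE_STEP = "not-single-step"


class FAParseError(ValueError):
    """Malformed fatty-acid shorthand."""


class FAValidationError(ValueError):
    """Well-formed shorthand describing a geometrically impossible PUFA."""


class ClassificationError(ValueError):
    """Substrate/product pair that cannot be compared (e.g. series mismatch)."""


# Accepts "24:5n-3", "24:5n−3" (Unicode minus), "24:5(n-3)", case-insensitive.
_FA_RE = re.compile(
    r"^\s*(\d+)\s*:\s*(\d+)\s*"
    r"(?:\(?\s*n\s*[-−–]\s*(\d+)\s*\)?)?\s*$",
    re.IGNORECASE,
)


@dataclass(frozen=True, order=True)
class FattyAcid:
    """A methylene-interrupted fatty acid in C:Dn-x shorthand.

    ``omega`` is None only for saturated acids (``double_bonds == 0``).
    """

    carbons: int
    double_bonds: int
    omega: Optional[int] = None

    def __post_init__(self) -> None:
        if self.carbons < 4 or self.carbons % 2:
            raise FAValidationError(
                f"carbon count must be even and >= 4, got {self.carbons}"
            )
        if self.double_bonds < 0:
            raise FAValidationError("double_bonds must be >= 0")
        if self.double_bonds == 0:
            if self.omega is not None:
                raise FAValidationError(
                    "saturated fatty acid cannot carry an n-x series"
                )
            return
        if self.omega is None or self.omega < 1:
            raise FAValidationError(
                f"unsaturated fatty acid requires omega >= 1, got {self.omega}"
            )
        # Proximal double bond must sit at Delta >= 2: the carboxyl carbon and
        # its alpha carbon cannot host a methylene-interrupted bond series.
        proximal = self.carbons - (self.omega + 3 * (self.double_bonds - 1))
        if proximal < 2:
            raise FAValidationError(
                f"{self.label}: methylene-interrupted geometry impossible "
                f"(proximal double bond would fall at Delta {proximal})"
            )

    @property
    def label(self) -> str:
        """Canonical ASCII shorthand, e.g. ``24:5n-3`` or ``18:0``."""
        if self.double_bonds == 0:
            return f"{self.carbons}:0"
        return f"{self.carbons}:{self.double_bonds}n-{self.omega}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_fa_shorthand(text: str) -> FattyAcid:
    """Parse ``C:Dn-x`` shorthand into a :class:`FattyAcid`.

    Accepts the ASCII hyphen, the Unicode minus/en-dash, and the
    parenthesised ``(n-x)`` dialect; the canonical label emitted on
    formatting is always ASCII ``C:Dn-x``.

    Raises
    ------
    FAParseError
        If the string does not match the shorthand grammar.
    FAValidationError
        If the shorthand describes an impossible methylene-interrupted PUFA.
    """
    m = _FA_RE.match(text)
    if not m:
        raise FAParseError(f"cannot parse fatty-acid shorthand {text!r}")
    carbons, dbonds = int(m.group(1)), int(m.group(2))
    omega = int(m.group(3)) if m.group(3) is not None else None
    if dbonds >= 1 and omega is None:
        raise FAParseError(
            f"{text!r}: unsaturated fatty acid requires an n-x series"
        )
    return FattyAcid(carbons=carbons, double_bonds=dbonds, omega=omega)


def delta_positions(fa: FattyAcid) -> list[int]:
    """Carboxyl-referenced double-bond positions, ascending.

    The terminal bond sits at ``C - omega``; methylene interruption places
    the others at 3-carbon intervals toward the carboxyl end.
    """
    if fa.double_bonds == 0:
        raise FAValidationError(f"{fa.label} is saturated: no double bonds")
    assert fa.omega is not None
    return sorted(
        fa.carbons - (fa.omega + 3 * i) for i in range(fa.double_bonds)
    )


def _positions_or_empty(fa: FattyAcid) -> set[int]:
    return set(delta_positions(fa)) if fa.double_bonds else set()


def classify_conversion(substrate: FattyAcid, product: FattyAcid) -> str:
    """Name the single enzymatic step turning ``substrate`` into ``product``.

    Returns ``"Δk"`` for a desaturation introducing a bond at Delta-k,
    ``"elongation"`` for a +2-carbon extension, ``"beta-oxidation"`` for a
    -2-carbon shortening, or ``"not-single-step"``.  Elongation and
    β-oxidation preserve both the bond count and the n-x series (positions
    are methyl-referenced, so they shift in Δ numbering but not in ω).
    """
    if (
        substrate.double_bonds
        and product.double_bonds
        and substrate.omega != product.omega
    ):
        raise ClassificationError(
            f"series mismatch: {substrate.label} is n-{substrate.omega}, "
            f"{product.label} is n-{product.omega}"
        )
    if (
        product.carbons == substrate.carbons
        and product.double_bonds == substrate.double_bonds + 1
    ):
        new = _positions_or_empty(product) - _positions_or_empty(substrate)
        if len(new) == 1 and _positions_or_empty(substrate) <= _positions_or_empty(product):
            return f"Δ{new.pop()}"
        return NOT_SINGLE_STEP
    if (
        product.double_bonds == substrate.double_bonds
        and product.omega == substrate.omega
    ):
        if product.carbons == substrate.carbons + 2:
            return ELONGATION
        if product.carbons == substrate.carbons - 2:
            return BETA_OXIDATION
    return NOT_SINGLE_STEP


class PathwayGraph:
    """Directed graph of fatty acids connected by single enzymatic steps.

    Every edge label is checked against :func:`classify_conversion` on
    insertion, so the graph cannot hold a mislabeled step.
    """

    def __init__(self) -> None:
        self.nodes: set[FattyAcid] = set()
        self._edges: list[tuple[FattyAcid, FattyAcid, str]] = []

    def add_edge(self, substrate: FattyAcid, product: FattyAcid) -> str:
        activity = classify_conversion(substrate, product)
        if activity == NOT_SINGLE_STEP:
            raise ClassificationError(
                f"{substrate.label} -> {product.label} is not a single "
                "enzymatic step"
            )
        self.nodes.update((substrate, product))
        self._edges.append((substrate, product, activity))
        return activity

    @property
    def edges(self) -> list[tuple[FattyAcid, FattyAcid, str]]:
        return list(self._edges)

    def has_edge(self, substrate: FattyAcid, product: FattyAcid) -> bool:
        return any(s == substrate and p == product for s, p, _ in self._edges)

    def edge_activity(self, substrate: FattyAcid, product: FattyAcid) -> str:
        for s, p, a in self._edges:
            if s == substrate and p == product:
                return a
        raise KeyError(f"no edge {substrate.label} -> {product.label}")

    def successors(self, fa: FattyAcid) -> Iterator[tuple[FattyAcid, str]]:
        for s, p, a in self._edges:
            if s == fa:
                yield p, a

    def activities(self) -> set[str]:
        return {a for _, _, a in self._edges}

    def subgraph(self, activities: set[str]) -> "PathwayGraph":
        """New graph keeping only edges with the given activity labels."""
        g = PathwayGraph()
        for s, p, a in self._edges:
            if a in activities:
                g.add_edge(s, p)
        return g

    # -- export ---------------------------------------------------------
    def to_tsv(self) -> str:
        lines = ["substrate\tproduct\tactivity"]
        lines += [f"{s.label}\t{p.label}\t{a}" for s, p, a in self._edges]
        return "\n".join(lines) + "\n"

    def to_dot(self) -> str:
        lines = ["digraph pufa_pathway {"]
        for s, p, a in self._edges:
            lines.append(f'  "{s.label}" -> "{p.label}" [label="{a}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def default_pathway_graph() -> PathwayGraph:
    """The accepted teleost LC-PUFA network for the n-3 and n-6 series.

    Per series: the Δ6 route (Δ6 – elongation – Δ5) and the Δ8 route
    (elongation – Δ8 – Δ5) to EPA/ARA, two downstream elongations to the
    C24 intermediate, the Sprecher terminus (Δ6 then partial β-oxidation),
    and the direct Δ4 desaturation of the C22 pentaene/tetraene.
    """
    g = PathwayGraph()
    fa = parse_fa_shorthand
    for omega in (3, 6):
        d = 3 if omega == 3 else 2  # 18:3n-3 / 18:2n-6 precursors
        c18 = fa(f"18:{d}n-{omega}")
        # Δ6 route to the C20 Δ5-substrate
        g.add_edge(c18, fa(f"18:{d + 1}n-{omega}"))
        g.add_edge(fa(f"18:{d + 1}n-{omega}"), fa(f"20:{d + 1}n-{omega}"))
        # Δ8 route to the same C20 Δ5-substrate
        g.add_edge(c18, fa(f"20:{d}n-{omega}"))
        g.add_edge(fa(f"20:{d}n-{omega}"), fa(f"20:{d + 1}n-{omega}"))
        # Δ5 desaturation -> EPA (n-3) / ARA (n-6)
        g.add_edge(fa(f"20:{d + 1}n-{omega}"), fa(f"20:{d + 2}n-{omega}"))
        # two downstream elongations to the C24 Sprecher substrate
        g.add_edge(fa(f"20:{d + 2}n-{omega}"), fa(f"22:{d + 2}n-{omega}"))
        g.add_edge(fa(f"22:{d + 2}n-{omega}"), fa(f"24:{d + 2}n-{omega}"))
        # Sprecher terminus: Δ6 then partial β-oxidation
        g.add_edge(fa(f"24:{d + 2}n-{omega}"), fa(f"24:{d + 3}n-{omega}"))
        g.add_edge(fa(f"24:{d + 3}n-{omega}"), fa(f"22:{d + 3}n-{omega}"))
        # direct Δ4 route
        g.add_edge(fa(f"22:{d + 2}n-{omega}"), fa(f"22:{d + 3}n-{omega}"))
    return g
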