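"""Conversion-efficiency statistics for heterologous desaturase assays.

In the yeast assay a desaturase (optionally co-expressed with an elongase)
is grown with an exogenous fatty-acid substrate; the GC peak areas of the
substrate and its products quantify each enzymatic step as

    conversion % = product area / (product area + substrate area) * 100.

For chained assays the "product area" of a step is the area of the
immediate product plus everything derived from it further downstream (a
product consumed by the next step still counts toward the step that made
it), while the substrate term is the substrate's own remaining peak.  This
makes each step's conversion equal the fraction of the substrate pool the
step actually turned over.

Activities on the C24 Sprecher substrate 24:5n-3 are normalised across
enzymes by the ratio of that conversion to the conversion of the enzyme's
control substrate (Δ_24:5n-3 / Δ_control).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

from .fa import (
    BETA_OXIDATION,
    FattyAcid,
    PathwayGraph,
    classify_conversion,
    parse_fa_shorthand,
)

__all__ = [
    "ND",
    "PeakTable",
    "ConversionResult",
    "ActivityReport",
    "UndefinedConversionError",
    "UndefinedRatioError",
    "conversion_percent",
    "chain_conversions",
    "normalized_ratio",
    "build_activity_table",
    "round_half_up",
    "read_input_tsv",
    "report_to_tsv",
    "report_to_json",
]

#: Sentinel for a peak below the detection floor ("not detected").
ND = None


class UndefinedConversionError(ValueError):
    """Both substrate and product areas are zero: 0/0, not ND."""


class UndefinedRatioError(ValueError):
    """Control conversion is ND or zero while the numerator is measurable."""


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal round-half-up (0.825 -> 0.83), as printed activity tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def conversion_percent(substrate_area: float, product_area: float) -> float:
    """[product / (product + substrate)] x 100, in [0, 100].

    Scale-invariant: multiplying both areas by a common factor leaves the
    result unchanged.
    """
    if substrate_area < 0 or product_area < 0:
        raise ValueError("peak areas must be non-negative")
    total = substrate_area + product_area
    if total == 0:
        raise UndefinedConversionError(
            "both substrate and product areas are zero"
        )
    # divide first so the quotient is capped at 1.0 in floating point
    return 100.0 * (product_area / total)


@dataclass
class PeakTable:
    """Measured peak areas of one assay culture.

    ``areas`` maps canonical fatty-acid labels to chromatographic peak
    areas (arbitrary units).  ``detection_floor`` is the area below which a
    peak is reported as not detected.
    """

    assay_id: str
    areas: Mapping[str, float]
    exogenous_substrate: FattyAcid
    detection_floor: float = 0.0

    def __post_init__(self) -> None:
        for label, area in self.areas.items():
            if area < 0:
                raise ValueError(f"negative area for {label}")
        if self.exogenous_substrate.label not in self.areas:
            raise ValueError(
                f"exogenous substrate {self.exogenous_substrate.label} "
                "missing from peak table"
            )

    def area(self, fa: FattyAcid) -> float:
        return float(self.areas.get(fa.label, 0.0))

    def detected(self, fa: FattyAcid) -> bool:
        return self.area(fa) > self.detection_floor


@dataclass
class ConversionResult:
    substrate: FattyAcid
    product: FattyAcid
    activity: str
    percent: Optional[float]  # None == ND

    def __post_init__(self) -> None:
        if self.percent is not None and not 0.0 <= self.percent <= 100.0:
            raise ValueError("conversion percent outside [0, 100]")
        expected = classify_conversion(self.substrate, self.product)
        if expected != self.activity:
            raise ValueError(
                f"activity {self.activity!r} inconsistent with pair "
                f"({self.substrate.label}, {self.product.label}): {expected}"
            )


def chain_conversions(
    table: PeakTable,
    graph: PathwayGraph,
    include_beta_oxidation: bool = False,
) -> list[ConversionResult]:
    """Per-step conversions along the pathway reachable from the substrate.

    Breadth-first walk from the exogenous substrate.  Each outgoing edge of
    a detected node yields one result: a numeric conversion when the product
    is detected, ND otherwise.  The product term of an edge is the product's
    area plus the areas of everything downstream of it that the walk
    reached, so endogenously produced intermediates consumed by later steps
    still count toward the step that produced them.  β-oxidation edges are
    skipped by default (yeast lack the peroxisomal step).
    """
    if table.exogenous_substrate not in graph.nodes:
        raise ValueError(
            f"exogenous substrate {table.exogenous_substrate.label} absent "
            "from pathway graph"
        )
    # BFS over detected nodes, collecting traversed edges once each.
    visited = {table.exogenous_substrate}
    queue = [table.exogenous_substrate]
    traversed: list[tuple[FattyAcid, FattyAcid, str]] = []
    seen_edges: set[tuple[FattyAcid, FattyAcid]] = set()
    while queue:
        node = queue.pop(0)
        for product, activity in graph.successors(node):
            if activity == BETA_OXIDATION and not include_beta_oxidation:
                continue
            if (node, product) in seen_edges:
                continue
            seen_edges.add((node, product))
            traversed.append((node, product, activity))
            if table.detected(product) and product not in visited:
                visited.add(product)
                queue.append(product)

    # Cumulative area of each reached node = own area + downstream areas
    # over traversed edges (the traversal is acyclic: chain lengths and bond
    # counts only move forward).
    children: dict[FattyAcid, list[FattyAcid]] = {}
    for s, p, _ in traversed:
        children.setdefault(s, []).append(p)

    def cumulative(fa: FattyAcid) -> float:
        return table.area(fa) + sum(cumulative(c) for c in children.get(fa, []))

    results: list[ConversionResult] = []
    for s, p, activity in traversed:
        if table.detected(p):
            pct = conversion_percent(table.area(s), cumulative(p))
        else:
            pct = ND
        results.append(ConversionResult(s, p, activity, pct))
    return results


def normalized_ratio(
    conv_24_5n3: Optional[float], conv_control: Optional[float]
) -> float:
    """Δ_24:5n-3 / Δ_control, rounded half-up to 2 decimals; ND numerator -> 0.00."""
    if conv_24_5n3 is ND:
        return 0.0
    if conv_control is ND or conv_control == 0:
        raise UndefinedRatioError(
            "control conversion is ND or zero while 24:5n-3 conversion "
            "is measurable"
        )
    if conv_24_5n3 < 0 or conv_control < 0:
        raise ValueError("conversions must be non-negative")
    return round_half_up(conv_24_5n3 / conv_control, 2)


@dataclass
class AssayRecord:
    """One desaturase's measured conversions and its control identity."""

    desaturase_id: str
    conv_24_4n6: Optional[float]
    conv_24_5n3: Optional[float]
    control_substrate: FattyAcid
    control_product: FattyAcid
    conv_control: Optional[float]


@dataclass
class ActivityReport:
    """A normalised activity-table row (conversions plus ratio)."""

    desaturase_id: str
    conv_24_4n6: Optional[float]
    conv_24_5n3: Optional[float]
    control_substrate: FattyAcid
    control_product: FattyAcid
    conv_control: Optional[float]
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        self.ratio = normalized_ratio(self.conv_24_5n3, self.conv_control)


def build_activity_table(records: Iterable[AssayRecord]) -> list[ActivityReport]:
    """One report row per desaturase, input order preserved."""
    reports: list[ActivityReport] = []
    seen: set[str] = set()
    for rec in records:
        if rec.desaturase_id in seen:
            raise ValueError(f"duplicate desaturase_id {rec.desaturase_id!r}")
        seen.add(rec.desaturase_id)
        reports.append(
            ActivityReport(
                desaturase_id=rec.desaturase_id,
                conv_24_4n6=rec.conv_24_4n6,
                conv_24_5n3=rec.conv_24_5n3,
                control_substrate=rec.control_substrate,
                control_product=rec.control_product,
                conv_control=rec.conv_control,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# Tabular I/O


def _parse_percent(token: str) -> Optional[float]:
    token = token.strip()
    if token.upper() == "ND" or token == "":
        return ND
    return float(token)


def _fmt_percent(value: Optional[float], ndigits: int = 1) -> str:
    if value is ND:
        return "ND"
    return f"{round_half_up(value, ndigits):.{ndigits}f}"


def read_input_tsv(path) -> list[AssayRecord] | list[PeakTable]:
    """Read an assay input TSV in either supported dialect.

    Long format (raw areas): columns ``assay_id``, ``desaturase_id``,
    ``fa_label``, ``peak_area`` -> list of :class:`PeakTable` (the first
    fa_label of each assay is taken as the exogenous substrate).
    Wide format (pre-computed conversions): columns ``desaturase_id``,
    ``conv_24_4n6``, ``conv_24_5n3``, ``control_label``,
    ``control_product``, ``conv_control`` -> list of :class:`AssayRecord`.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = set(df.columns)
    if "peak_area" in cols:
        required = {"assay_id", "desaturase_id", "fa_label", "peak_area"}
        if not required <= cols:
            raise ValueError(
                f"long-format TSV missing columns {sorted(required - cols)}"
            )
        tables = []
        for assay_id, grp in df.groupby("assay_id", sort=False):
            areas = {
                parse_fa_shorthand(r.fa_label).label: float(r.peak_area)
                for r in grp.itertuples()
            }
            substrate = parse_fa_shorthand(grp.iloc[0]["fa_label"])
            tables.append(PeakTable(str(assay_id), areas, substrate))
        return tables
    required = {
        "desaturase_id",
        "conv_24_4n6",
        "conv_24_5n3",
        "control_label",
        "conv_control",
    }
    if not required <= cols:
        raise ValueError(
            f"TSV matches neither dialect; missing {sorted(required - cols)}"
        )
    records = []
    for r in df.itertuples():
        control = parse_fa_shorthand(r.control_label)
        if "control_product" in cols:
            product = parse_fa_shorthand(r.control_product)
        else:
            product = FattyAcid(
                control.carbons, control.double_bonds + 1, control.omega
            )
        records.append(
            AssayRecord(
                desaturase_id=r.desaturase_id,
                conv_24_4n6=_parse_percent(r.conv_24_4n6),
                conv_24_5n3=_parse_percent(r.conv_24_5n3),
                control_substrate=control,
                control_product=product,
                conv_control=_parse_percent(r.conv_control),
            )
        )
    return records


def report_to_tsv(reports: Sequence[ActivityReport]) -> str:
    """Activity table as TSV, conversions at 1 dp and ratios at 2 dp."""
    lines = [
        "desaturase_id\tconv_24_4n6\tconv_24_5n3\tcontrol\tconv_control\tratio"
    ]
    for r in reports:
        lines.append(
            "\t".join(
                [
                    r.desaturase_id,
                    _fmt_percent(r.conv_24_4n6),
                    _fmt_percent(r.conv_24_5n3),
                    f"{r.control_substrate.label}->{r.control_product.label}",
                    _fmt_percent(r.conv_control),
                    f"{r.ratio:.2f}",
                ]
            )
        )
    return "\n".join(lines) + "\n"


def report_to_json(reports: Sequence[ActivityReport]) -> str:
    """Full-precision JSON report (ND encoded as null)."""
    payload = [
        {
            "desaturase_id": r.desaturase_id,
            "conv_24_4n6": r.conv_24_4n6,
            "conv_24_5n3": r.conv_24_5n3,
            "control_substrate": r.control_substrate.label,
            "control_product": r.control_product.label,
            "conv_control": r.conv_control,
            "ratio": r.ratio,
        }
        for r in reports
    ]
    return json.dumps(payload, indent=2)
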