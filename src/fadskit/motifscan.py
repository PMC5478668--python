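"""Δ4-desaturase signature discovery by wildcard motif scanning.

Teleost Fads2 desaturases with Δ4 regioselectivity carry a conserved region
(consensus ``PPLLIPVFYNFNIMXTMISR``) containing the four-residue YXXN
domain; the Y and N at positions 1 and 4 of that domain are required for Δ4
function.  This module derives such a consensus query from a seed alignment
of characterised Δ4 enzymes, scans candidate proteins with exhaustive
wildcard-aware window matching, and calls putative Δ4 desaturases by
requiring both an overall match within a mismatch ceiling and intact Y/N
anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "WILDCARD",
    "DEFAULT_QUERY",
    "DEFAULT_MAX_MISMATCHES",
    "MotifQuery",
    "ScanHit",
    "Delta4Call",
    "MotifDerivationError",
    "consensus_query",
    "scan_protein",
    "call_putative_delta4",
    "read_protein_fasta",
    "calls_to_tsv",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
WILDCARD = "X"
#: Residues that never match a non-wildcard query position.
_NONSTANDARD = set("BZJUO*")

#: Mismatch ceiling over the query's non-wildcard positions (the Y/N
#: anchors are mandatory regardless of this ceiling).
DEFAULT_MAX_MISMATCHES = 6

PUTATIVE_D4 = "putative-Δ4"
NON_D4 = "non-Δ4"
NO_HIT = "no-hit"


class MotifDerivationError(ValueError):
    """Seed consensus lacks a Y..N anchor pair at spacing 3."""


@dataclass(frozen=True)
class MotifQuery:
    """Consensus query over the amino-acid alphabet plus wildcard ``X``.

    ``y_anchor`` is the 0-based offset of the YXXN domain's Y; the N sits
    at ``y_anchor + 3``.
    """

    sequence: str
    y_anchor: int

    def __post_init__(self) -> None:
        seq = self.sequence
        if len(seq) < 4:
            raise ValueError("query must be at least 4 residues")
        bad = set(seq) - set(AMINO_ACIDS) - {WILDCARD}
        if bad:
            raise ValueError(f"invalid query residues {sorted(bad)}")
        if not (0 <= self.y_anchor and self.y_anchor + 3 < len(seq)):
            raise ValueError("y_anchor+3 must fall inside the query")
        if seq[self.y_anchor] != "Y" or seq[self.y_anchor + 3] != "N":
            raise ValueError(
                "query must carry Y at y_anchor and N at y_anchor+3"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_scored(self) -> int:
        """Number of non-wildcard positions (mismatch/identity denominator)."""
        return sum(1 for c in self.sequence if c != WILDCARD)


def default_query() -> MotifQuery:
    """The published 20-residue Δ4 consensus with the YXXN domain at 8–11."""
    return MotifQuery("PPLLIPVFYNFNIMXTMISR", y_anchor=8)


DEFAULT_QUERY = default_query()


@dataclass(frozen=True)
class ScanHit:
    subject_id: str
    start: int  # 0-based window start
    window: str
    mismatches: int
    yxxn_pass: bool
    identity: float


@dataclass(frozen=True)
class Delta4Call:
    subject_id: str
    best_hit: Optional[ScanHit]
    verdict: str  # PUTATIVE_D4 | NON_D4 | NO_HIT


def consensus_query(
    seeds: Sequence[str], window: Optional[tuple[int, int]] = None
) -> MotifQuery:
    """Column-wise consensus of aligned seed sequences.

    A column where all seeds agree on one residue (no gaps) emits that
    residue; disagreement or any gap emits the wildcard ``X`` (keeping the
    query length, and hence anchor arithmetic, stable).  The YXXN anchor is
    the first emitted ``Y`` with an ``N`` three positions later.
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seed sequences")
    lengths = {len(s) for s in seeds}
    if len(lengths) != 1:
        raise ValueError("seed sequences must have equal aligned length")
    (aln_len,) = lengths
    lo, hi = window if window is not None else (0, aln_len)
    if not (0 <= lo < hi <= aln_len):
        raise ValueError(f"window ({lo}, {hi}) outside alignment of length {aln_len}")
    consensus = []
    for col in range(lo, hi):
        residues = {s[col].upper() for s in seeds}
        if len(residues) == 1 and "-" not in residues:
            consensus.append(residues.pop())
        else:
            consensus.append(WILDCARD)
    pattern = "".join(consensus)
    for i in range(len(pattern) - 3):
        if pattern[i] == "Y" and pattern[i + 3] == "N":
            return MotifQuery(pattern, y_anchor=i)
    raise MotifDerivationError(
        f"consensus {pattern!r} contains no conserved Y..N pair at spacing "
        "3; widen the window to cover the YXXN domain"
    )


def scan_protein(
    subject: str,
    query: MotifQuery = DEFAULT_QUERY,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    subject_id: str = "",
) -> list[ScanHit]:
    """All windows of ``subject`` matching ``query`` within the ceiling.

    Wildcard query positions match anything and are excluded from both the
    mismatch count and the identity denominator; non-standard subject
    residues (B, Z, J, U, O, *) never match.  Hits are sorted by
    (mismatches, start).
    """
    subject = subject.upper()
    q = query.sequence
    scored = [i for i, c in enumerate(q) if c != WILDCARD]
    n_scored = len(scored)
    if len(subject) < query.length:
        logger.info(
            "subject %s shorter than query (%d < %d); no windows scanned",
            subject_id or "<anonymous>",
            len(subject),
            query.length,
        )
        return []
    hits = []
    for start in range(len(subject) - query.length + 1):
        window = subject[start : start + query.length]
        mismatches = sum(
            1
            for i in scored
            if window[i] != q[i] or window[i] in _NONSTANDARD
        )
        if mismatches <= max_mismatches:
            hits.append(
                ScanHit(
                    subject_id=subject_id,
                    start=start,
                    window=window,
                    mismatches=mismatches,
                    yxxn_pass=(
                        window[query.y_anchor] == "Y"
                        and window[query.y_anchor + 3] == "N"
                    ),
                    identity=(n_scored - mismatches) / n_scored,
                )
            )
    hits.sort(key=lambda h: (h.mismatches, h.start))
    return hits


def call_putative_delta4(
    candidates: Iterable[tuple[str, str]],
    query: MotifQuery = DEFAULT_QUERY,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> list[Delta4Call]:
    """Classify each candidate protein by its best signature hit.

    ``candidates`` yields (id, sequence) pairs (see
    :func:`read_protein_fasta`).  The best hit is the one with fewest
    mismatches, ties broken leftmost.  Verdict is putative-Δ4 iff a hit
    exists within the ceiling and its Y/N anchors are intact.
    """
    calls = []
    seen: set[str] = set()
    for subject_id, seq in candidates:
        if subject_id in seen:
            raise ValueError(f"duplicate FASTA id {subject_id!r}")
        seen.add(subject_id)
        hits = scan_protein(seq, query, max_mismatches, subject_id=subject_id)
        if not hits:
            calls.append(Delta4Call(subject_id, None, NO_HIT))
            continue
        best = hits[0]
        verdict = PUTATIVE_D4 if best.yxxn_pass else NON_D4
        calls.append(Delta4Call(subject_id, best, verdict))
    return calls


def read_protein_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """FASTA records as (id, sequence) pairs; ids must be unique."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids {dupes}")
    return records


def calls_to_tsv(calls: Sequence[Delta4Call]) -> str:
    """Per-candidate report; window coordinates are 1-based."""
    lines = ["subject_id\tstart_1based\twindow\tmismatches\tidentity\tyxxn_pass\tverdict"]
    for c in calls:
        if c.best_hit is None:
            lines.append(f"{c.subject_id}\t.\t.\t.\t.\t.\t{c.verdict}")
        else:
            h = c.best_hit
            lines.append(
                f"{c.subject_id}\t{h.start + 1}\t{h.window}\t{h.mismatches}"
                f"\t{h.identity:.3f}\t{str(h.yxxn_pass).lower()}\t{c.verdict}"
            )
    return "\n".join(lines) + "\n"
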