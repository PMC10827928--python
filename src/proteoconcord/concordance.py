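"""Cross-disease concordance classification of matched differential tables.

The anchor table (disease A, e.g. epilepsy hippocampus) is matched record by
record against the consistency calls of disease B (e.g. the NeuroPro
advanced-AD meta-analysis) using the dual-identifier rule. Every anchor
protein lands in exactly one category:

``same_up`` / ``same_down``
    significantly altered in the same direction in both diseases;
``opposite``
    altered in both but in opposite directions;
``inconsistent_b``
    matched to a B protein whose prior-study directions disagree, so no
    cross-disease direction comparison is possible;
``a_only``
    no match in B.

Category counts always partition the anchor table, so headline fractions
("89% (689/777) also altered in AD", "49% (340/689) same direction")
reconcile exactly. Records can additionally be annotated against curated
reference sets (causative genes, tau interactors, lesion-enriched proteins).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .consistency import DirectionCall
from .tables_io import DiffTable, KeyIndex, ProteinKey, ReferenceSet

__all__ = [
    "ConcordanceRecord",
    "ConcordanceSummary",
    "calls_from_table",
    "match_tables",
    "annotate",
    "summarize",
    "records_to_frame",
    "round_half_up_percent",
]

CATEGORIES = ("same_up", "same_down", "opposite", "inconsistent_b", "a_only")


@dataclass
class ConcordanceRecord:
    """One anchor-table protein with its cross-disease category."""

    key: ProteinKey
    dir_a: str  # "up" | "down"
    call_b: DirectionCall | None  # None when unmatched
    category: str
    matched_key: ProteinKey | None = None
    annotations: set[str] = field(default_factory=set)


@dataclass
class ConcordanceSummary:
    n_a: int
    n_matched: int
    n_same: int
    n_same_up: int
    n_same_down: int
    n_opposite: int
    n_inconsistent_b: int
    n_a_only: int
    pct_matched: int
    pct_same_of_matched: int
    reference_overlaps: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def round_half_up_percent(numerator: int, denominator: int) -> int:
    """Integer percent with conventional half-up rounding (688.5/777 → 89)."""
    if denominator == 0:
        return 0
    return int(100.0 * numerator / denominator + 0.5)


def calls_from_table(table: DiffTable) -> dict[ProteinKey, DirectionCall]:
    """Treat a single-study differential table as unit-score direction calls.

    Used when disease B is itself one differential table rather than a
    multi-study meta-resource: every record becomes a consistent call of
    score ±1 in its direction.
    """
    return {
        r.key: DirectionCall("increased", 1) if r.direction == "up" else DirectionCall("decreased", -1)
        for r in table.records
    }


def _categorise(dir_a: str, call_b: DirectionCall) -> str:
    if call_b.call == "inconsistent":
        return "inconsistent_b"
    sign_a = 1 if dir_a == "up" else -1
    if sign_a == call_b.sign:
        return "same_up" if sign_a > 0 else "same_down"
    return "opposite"


def match_tables(
    a: DiffTable, b_calls: Mapping[ProteinKey, DirectionCall]
) -> list[ConcordanceRecord]:
    """Match every record of the anchor table against B's direction calls.

    Matching resolves by accession first, then gene symbol; it never chains
    through intermediates. Several anchor records may match the same B
    protein — each simply inherits that B call (set semantics).
    """
    index = KeyIndex(b_calls.keys())
    out: list[ConcordanceRecord] = []
    for rec in a.records:
        hit = index.find(rec.key)
        if hit is None:
            out.append(ConcordanceRecord(rec.key, rec.direction, None, "a_only"))
        else:
            call = b_calls[hit]
            out.append(
                ConcordanceRecord(
                    rec.key, rec.direction, call, _categorise(rec.direction, call), matched_key=hit
                )
            )
    return out


def annotate(
    records: Sequence[ConcordanceRecord], reference_sets: Sequence[ReferenceSet]
) -> list[ConcordanceRecord]:
    """Fill each record's annotations with every reference set it matches."""
    indexes = [(rs.name, KeyIndex(rs.keys)) for rs in reference_sets]
    for rec in records:
        for name, idx in indexes:
            if rec.key in idx:
                rec.annotations.add(name)
    return list(records)


def summarize(records: Sequence[ConcordanceRecord]) -> ConcordanceSummary:
    """Tally categories and per-reference-set overlaps.

    Invariants: ``n_matched = n_same + n_opposite + n_inconsistent_b`` and
    ``n_a = n_matched + n_a_only``. Percentages are reported as integer
    percent, half-up.
    """
    counts = {c: 0 for c in CATEGORIES}
    ref_counts: dict[str, int] = {}
    for rec in records:
        counts[rec.category] += 1
        for name in rec.annotations:
            ref_counts[name] = ref_counts.get(name, 0) + 1
    n_a = len(records)
    n_matched = n_a - counts["a_only"]
    n_same = counts["same_up"] + counts["same_down"]
    return ConcordanceSummary(
        n_a=n_a,
        n_matched=n_matched,
        n_same=n_same,
        n_same_up=counts["same_up"],
        n_same_down=counts["same_down"],
        n_opposite=counts["opposite"],
        n_inconsistent_b=counts["inconsistent_b"],
        n_a_only=counts["a_only"],
        pct_matched=round_half_up_percent(n_matched, n_a),
        pct_same_of_matched=round_half_up_percent(n_same, n_matched),
        reference_overlaps=dict(sorted(ref_counts.items())),
    )


def records_to_frame(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    """One row per anchor protein: category, B call and annotation flags."""
    all_sets = sorted({name for r in records for name in r.annotations})
    rows = []
    for r in records:
        row = {
            "uniprot": r.key.uniprot,
            "gene": r.key.gene,
            "dir_a": r.dir_a,
            "call_b": r.call_b.call if r.call_b else "",
            "score_b": r.call_b.score if r.call_b and r.call_b.score is not None else "",
            "category": r.category,
        }
        for name in all_sets:
            row[f"in_{name}"] = name in r.annotations
        rows.append(row)
    return pd.DataFrame(rows)
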