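"""Directional-consistency scoring of multi-study evidence.

Meta-resources such as NeuroPro record, for each protein, every prior study
that reported it significantly altered in advanced AD brain, together with
the direction of the change. This module condenses such a vector of signed
reports into a single call:

* ``increased`` / ``decreased`` with a signed score when the reports are
  directionally consistent (or nearly so — one dissenting report is tolerated
  when the majority direction has more than five reports),
* ``inconsistent`` (no score) otherwise, including exact ties.

The score magnitude is the count of majority-direction reports; its sign
encodes the direction (negative = decreased).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .tables_io import ProteinKey

__all__ = ["DirectionCall", "StudyReportSet", "score_reports", "call_table", "call_counts"]

# a single dissenting report is permitted when the majority count exceeds this
EXCEPTION_THRESHOLD = 5


@dataclass(frozen=True)
class DirectionCall:
    """Consistency classification of one protein across prior studies."""

    call: str  # "increased" | "decreased" | "inconsistent"
    score: int | None = None

    def __post_init__(self):
        if self.call == "increased" and not (self.score and self.score > 0):
            raise ValueError("increased call requires a positive score")
        if self.call == "decreased" and not (self.score and self.score < 0):
            raise ValueError("decreased call requires a negative score")
        if self.call == "inconsistent" and self.score is not None:
            raise ValueError("inconsistent call carries no score")
        if self.call not in ("increased", "decreased", "inconsistent"):
            raise ValueError(f"unknown call {self.call!r}")

    @property
    def sign(self) -> int:
        """+1 / -1 for directional calls, 0 for inconsistent."""
        if self.call == "increased":
            return 1
        if self.call == "decreased":
            return -1
        return 0


StudyReportSet = Mapping[ProteinKey, Iterable[int]]


def score_reports(reports: Iterable[int]) -> DirectionCall:
    """Score one protein's vector of signed study reports (each in {+1, -1}).

    Let ``M`` be the majority-direction count and ``m`` the minority count.
    Unanimous vectors (``m == 0``) are called in their direction with score
    ``±M``. A single dissenting report (``m == 1``) is forgiven when
    ``M > 5``, keeping the majority call and score ``±M``. Everything else —
    including ties — is ``inconsistent`` with no score.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("empty report vector")
    n_up = 0
    n_down = 0
    for r in reports:
        if r == 1:
            n_up += 1
        elif r == -1:
            n_down += 1
        else:
            raise ValueError(f"report values must be +1 or -1, got {r!r}")
    big, small = max(n_up, n_down), min(n_up, n_down)
    if small == 0 or (small == 1 and big > EXCEPTION_THRESHOLD):
        if n_up > n_down:
            return DirectionCall("increased", big)
        return DirectionCall("decreased", -big)
    return DirectionCall("inconsistent")


def call_table(reports: StudyReportSet) -> dict[ProteinKey, DirectionCall]:
    """Score every protein in a report set; errors name the offending protein."""
    calls: dict[ProteinKey, DirectionCall] = {}
    for key, vec in reports.items():
        try:
            calls[key] = score_reports(vec)
        except ValueError as e:
            raise ValueError(f"{key}: {e}") from e
    return calls


def call_counts(calls: Mapping[ProteinKey, DirectionCall]) -> dict[str, int]:
    """Summary counts of increased / decreased / inconsistent calls."""
    out = {"increased": 0, "decreased": 0, "inconsistent": 0}
    for c in calls.values():
        out[c.call] += 1
    return out
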