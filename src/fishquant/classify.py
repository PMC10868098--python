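"""ASCO/CAP 2018 dual-probe ISH classification.

Samples are partitioned into Groups 1-5 by (HER2/CEP17 ratio, mean HER2
signals per cell): Group 1 (ratio >= 2.0, >= 4.0 signals/cell), Group 2
(ratio >= 2.0, < 4.0 — historically "monosomy"), Group 3 (ratio < 2.0,
>= 6.0), Group 4 (ratio < 2.0, 4.0 to < 6.0) and Group 5 (ratio < 2.0,
< 4.0).  Group 1 is ISH positive, Group 5 ISH negative, and Groups 2-4
require IHC adjudication: IHC 0/1+ is negative, 3+ positive, and 2+ falls
back on the guideline's concurrent-review outcome (Group 3 positive,
Groups 2 and 4 negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

from .errors import IncompleteInputError, InvalidParameterError

GROUP_ANNOTATIONS = {2: "monosomy"}

#: guideline concurrent-review final call for IHC 2+ by group
_IHC2_DEFAULT = {2: "negative", 3: "positive", 4: "negative"}


def assign_group(ratio: float, her2_per_cell: float) -> int:
    """Dual-probe group (1-5) from the ratio and mean HER2 signals per cell.

    The Group 3/4 boundary at 6.0 signals/cell is resolved as Group 4 =
    [4.0, 6.0), Group 3 = [6.0, inf) so the partition is disjoint.
    """
    if ratio < 0 or her2_per_cell < 0:
        raise InvalidParameterError("ratio and her2_per_cell must be >= 0")
    if ratio >= 2.0:
        return 1 if her2_per_cell >= 4.0 else 2
    if her2_per_cell >= 6.0:
        return 3
    if her2_per_cell >= 4.0:
        return 4
    return 5


def ish_status(group: int) -> str:
    """ISH call for a group: 1 positive, 5 negative, 2-4 need IHC."""
    if group == 1:
        return "positive"
    if group == 5:
        return "negative"
    if group in (2, 3, 4):
        return "needs_ihc"
    raise InvalidParameterError(f"invalid group: {group}")


class OverallCall(NamedTuple):
    status: str
    guideline_default: bool


def integrate_ihc(group: int, ihc_score: Optional[int] = None) -> OverallCall:
    """Overall HER2 status integrating the ISH group with the IHC score.

    Groups 2-4 require an IHC score (0-3); ``guideline_default`` marks calls
    resolved by the guideline's IHC-2+ concurrent-review outcome.
    """
    status = ish_status(group)
    if status != "needs_ihc":
        return OverallCall(status, False)
    if ihc_score is None:
        raise IncompleteInputError(f"group {group} requires an IHC score")
    if ihc_score not in (0, 1, 2, 3):
        raise InvalidParameterError(f"invalid IHC score: {ihc_score}")
    if ihc_score in (0, 1):
        return OverallCall("negative", False)
    if ihc_score == 3:
        return OverallCall("positive", False)
    return OverallCall(_IHC2_DEFAULT[group], True)


@dataclass
class ASCOCAPResult:
    """Full dual-probe classification of one sample."""

    group: int
    ish_status: str
    overall_status: str
    ratio: float
    her2_per_cell: float
    ihc_score: Optional[int] = None
    annotation: Optional[str] = None
    guideline_default: bool = False

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "ish_status": self.ish_status,
            "overall_status": self.overall_status,
            "ratio": self.ratio,
            "her2_per_cell": self.her2_per_cell,
            "ihc_score": self.ihc_score,
            "annotation": self.annotation,
            "guideline_default": self.guideline_default,
        }


def classify_sample(
    ratio: float,
    her2_per_cell: float,
    ihc_score: Optional[int] = None,
) -> ASCOCAPResult:
    """Group assignment, ISH status and (if resolvable) overall HER2 status.

    When a group 2-4 sample comes without an IHC score the overall status is
    "indeterminate" rather than an error, so cohort tabulation can proceed.
    """
    group = assign_group(ratio, her2_per_cell)
    ish = ish_status(group)
    if ish == "needs_ihc" and ihc_score is None:
        overall, default = "indeterminate", False
    else:
        overall, default = integrate_ihc(group, ihc_score)
    return ASCOCAPResult(
        group=group,
        ish_status=ish,
        overall_status=overall,
        ratio=ratio,
        her2_per_cell=her2_per_cell,
        ihc_score=ihc_score,
        annotation=GROUP_ANNOTATIONS.get(group),
        guideline_default=default,
    )
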