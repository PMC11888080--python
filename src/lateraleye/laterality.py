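"""Claim-level laterality: side summaries, the 9-subgroup partition,
study-population filtering, and the rule-based mismatch flag.

A claim's *procedure side* is LEFT when every lateralized procedure code is
left-sided (and at least one exists), RIGHT symmetrically, BOTH when a
bilateral code is present or both sides appear, and INDETERMINATE when no
procedure carries side information.  The *diagnosis side* is computed the
same way over diagnosis codes; codes documented with an unspecified side or
without laterality are ignored for side determination (they carry no side
evidence, not conflicting evidence).

Crossing the two sides over {LEFT, RIGHT, BOTH} yields the nine subgroups
RR, RL, RB, LR, LL, LB, BR, BL, BB; the two discordant subgroups LR and RL
(procedure on one side, every lateralized diagnosis on the other) are the
wrong-site candidates the rule-based method flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

from lateraleye.claims_model import (
    ClaimSet,
    CodeMap,
    CodeMeta,
    CodedClaim,
    Laterality,
    System,
)

__all__ = [
    "Side",
    "Subgroup",
    "LateralitySummary",
    "SelectionFlow",
    "StudyPopulation",
    "code_laterality",
    "claim_sides",
    "assign_subgroup",
    "filter_study_population",
    "rule_flag",
]


class Side(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    BOTH = "BOTH"
    INDETERMINATE = "INDETERMINATE"


class Subgroup(str, Enum):
    """Procedure-side x diagnosis-side label (first letter = procedure)."""

    RR = "RR"
    RL = "RL"
    RB = "RB"
    LR = "LR"
    LL = "LL"
    LB = "LB"
    BR = "BR"
    BL = "BL"
    BB = "BB"
    INDETERMINATE = "INDETERMINATE"


DISCORDANT = frozenset({Subgroup.LR, Subgroup.RL})

_SIDE_LETTER = {Side.LEFT: "L", Side.RIGHT: "R", Side.BOTH: "B"}


@dataclass(frozen=True)
class LateralitySummary:
    procedure_side: Side
    diagnosis_side: Side


def code_laterality(code: str, code_map: CodeMap, system: System = System.PCS) -> CodeMeta:
    """Resolve one code's body part and laterality through the map (total)."""
    return code_map.resolve(code, system)


def _aggregate_side(metas: Iterable[CodeMeta]) -> Side:
    has_left = has_right = has_bilateral = False
    for meta in metas:
        if meta.laterality is Laterality.LEFT:
            has_left = True
        elif meta.laterality is Laterality.RIGHT:
            has_right = True
        elif meta.laterality is Laterality.BILATERAL:
            has_bilateral = True
    if has_bilateral or (has_left and has_right):
        return Side.BOTH
    if has_left:
        return Side.LEFT
    if has_right:
        return Side.RIGHT
    return Side.INDETERMINATE


def claim_sides(claim: CodedClaim, code_map: CodeMap) -> LateralitySummary:
    """Deterministic side summary of a claim's procedure and diagnosis codes."""
    proc = _aggregate_side(code_map.resolve(c, System.PCS) for c in claim.procedure_codes)
    diag = _aggregate_side(code_map.resolve(c, System.CM) for c in claim.diagnosis_codes)
    return LateralitySummary(procedure_side=proc, diagnosis_side=diag)


def assign_subgroup(claim: CodedClaim, code_map: CodeMap) -> Subgroup:
    """Total partition of claims into the 9 side-pair subgroups (+ INDETERMINATE)."""
    sides = claim_sides(claim, code_map)
    if sides.procedure_side is Side.INDETERMINATE or sides.diagnosis_side is Side.INDETERMINATE:
        return Subgroup.INDETERMINATE
    return Subgroup(_SIDE_LETTER[sides.procedure_side] + _SIDE_LETTER[sides.diagnosis_side])


def rule_flag(claim: CodedClaim, code_map: CodeMap) -> bool:
    """The rule-based wrong-site flag: laterality conflict (LR or RL subgroup)."""
    return assign_subgroup(claim, code_map) in DISCORDANT


# ---------------------------------------------------------------------------
# Study-population selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionFlow:
    """Counts at each selection stage, in filter order: specialty match ->
    identifiable laterality on both sides -> infusion-device-only exclusion."""

    total: int = 0
    specialty_matched: int = 0
    with_laterality_info: int = 0
    retained: int = 0
    subgroup_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "specialty_matched": self.specialty_matched,
            "with_laterality_info": self.with_laterality_info,
            "retained": self.retained,
            "subgroup_counts": dict(sorted(self.subgroup_counts.items())),
        }


@dataclass
class StudyPopulation:
    claims: ClaimSet
    flow: SelectionFlow


def filter_study_population(
    claims: ClaimSet, code_map: CodeMap, specialty: str
) -> StudyPopulation:
    """Select the analyzable population.

    Retains claims that (a) carry the configured attending-physician
    specialty code, (b) have at least one procedure *and* one diagnosis that
    resolve to an identifiable body part with side information
    (left/right/bilateral), and (c) are not infusion-device insertions only.
    Returns the retained claims together with a stage-by-stage count flow.
    """
    flow = SelectionFlow(total=len(claims))
    retained: list[CodedClaim] = []
    for claim in claims:
        if claim.specialty_code != specialty:
            continue
        flow.specialty_matched += 1
        proc_metas = [code_map.resolve(c, System.PCS) for c in claim.procedure_codes]
        diag_metas = [code_map.resolve(c, System.CM) for c in claim.diagnosis_codes]
        if not any(m.is_lateralized and m.body_part for m in proc_metas):
            continue
        if not any(m.is_lateralized and m.body_part for m in diag_metas):
            continue
        flow.with_laterality_info += 1
        if all(m.is_infusion_device_insertion for m in proc_metas):
            continue
        flow.retained += 1
        retained.append(claim)
        label = assign_subgroup(claim, code_map).value
        flow.subgroup_counts[label] = flow.subgroup_counts.get(label, 0) + 1
    return StudyPopulation(
        ClaimSet(retained, provenance=f"{claims.provenance} [specialty={specialty}]"), flow
    )
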