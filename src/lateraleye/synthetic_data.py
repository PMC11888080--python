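"""Condition-first synthetic claims generator with full ground truth.

Each synthetic claim is built from a latent orthopedic *condition* (a body
part and a side).  The condition emits a justifying diagnosis — documented
exactly, with an unspecified side, without laterality, as a general
diagnosis (gangrene-style codes that justify surgery without naming a body
part), or at a proximate body part — and the matching procedure.  With
probability ``p_wrong_site`` the procedure is corrupted: its side is flipped
(same-body-part error) or it is moved to a distant body part with the
opposite side (different-body-part error).  Unrelated comorbidity diagnoses
are appended, a configurable fraction of which are lateralized codes for
random body parts (resolved prior conditions); these are what make purely
rule-based laterality matching imprecise.  Because the corpus is
condition-first, procedure-diagnosis association is a real statistical
property of the data, which lets the association model be validated by
parameter recovery.

The synthetic code grammar mimics the shape of real codes without copying
any dictionary: procedures are 7-character PCS-like strings ``0S<part><side>0ZZ``,
diagnoses are CM-like strings (``M<part><side-digit>`` lateralized,
``M<part>9`` unspecified side, ``Z<part>0`` no laterality, ``G<cluster>0``
general, ``I<k>9`` comorbidities).  General codes are linked to clusters of
adjacent body parts — gangrene explains leg surgery, not shoulder surgery —
so that "a general diagnosis substantiates the procedure" is a learnable
co-occurrence pattern and not a modeling convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from lateraleye.claims_model import (
    ClaimSet,
    CodeMap,
    CodeMeta,
    CodedClaim,
    Laterality,
    System,
)

__all__ = [
    "ErrorKind",
    "NonErrorKind",
    "GroundTruth",
    "GeneratorConfig",
    "SyntheticUniverse",
    "build_code_universe",
    "simulate_claims",
    "truth_summary",
    "NONERROR_PRIORITY",
]

_PART_CHARS = "0123456789ABCDEFGHJKLMNPQRSTUVWXYZ"
_SIDE_CHAR = {0: "R", 1: "L"}  # internal side encoding: 0=right, 1=left
_SIDE_DIGIT = {0: "1", 1: "2"}  # CM convention: ...1 right, ...2 left
_SIDE_LAT = {0: Laterality.RIGHT, 1: Laterality.LEFT}


class ErrorKind(str, Enum):
    SAME_BODY_PART = "SAME_BODY_PART"
    DIFFERENT_BODY_PART = "DIFFERENT_BODY_PART"
    NONE = "NONE"


class NonErrorKind(str, Enum):
    UNSPECIFIED_SIDE = "UNSPECIFIED_SIDE"
    NO_LATERALITY = "NO_LATERALITY"
    GENERAL_DIAGNOSIS = "GENERAL_DIAGNOSIS"
    PROXIMITY = "PROXIMITY"
    COMBINATION = "COMBINATION"
    NONE = "NONE"


#: Weakest-justification ordering used to label a nonerror claim with the
#: rationale that made it survive review (NONE = exact match, strongest).
NONERROR_PRIORITY = [
    NonErrorKind.NONE,
    NonErrorKind.UNSPECIFIED_SIDE,
    NonErrorKind.NO_LATERALITY,
    NonErrorKind.GENERAL_DIAGNOSIS,
    NonErrorKind.PROXIMITY,
    NonErrorKind.COMBINATION,
]


@dataclass(frozen=True)
class GroundTruth:
    """Per-claim generator bookkeeping: what actually happened."""

    is_error: bool
    error_kind: ErrorKind = ErrorKind.NONE
    nonerror_kind: NonErrorKind = NonErrorKind.NONE
    justifying_diagnosis_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.is_error:
            if self.error_kind is ErrorKind.NONE or self.nonerror_kind is not NonErrorKind.NONE:
                raise ValueError("an error claim needs an error kind and no nonerror kind")
        elif self.error_kind is not ErrorKind.NONE:
            raise ValueError("a nonerror claim cannot carry an error kind")

    def to_dict(self) -> dict:
        return {
            "is_error": self.is_error,
            "error_kind": self.error_kind.value,
            "nonerror_kind": self.nonerror_kind.value,
            "justifying_diagnosis_index": self.justifying_diagnosis_index,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "GroundTruth":
        return cls(
            is_error=bool(data["is_error"]),
            error_kind=ErrorKind(data.get("error_kind", "NONE")),
            nonerror_kind=NonErrorKind(data.get("nonerror_kind", "NONE")),
            justifying_diagnosis_index=data.get("justifying_diagnosis_index"),
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Probabilities refer to one claim's justifying diagnosis unless noted.
    The documentation-noise parameters are ``p_unspecified_side``,
    ``p_no_laterality``, ``p_general_justification``, ``p_proximity_pair``
    and ``p_lateralized_comorbidity``: with all five at zero every claim is
    an exactly documented condition and review labels are fully determined.
    """

    n_claims: int = 100_000
    n_body_parts: int = 24
    mean_extra_diagnoses: float = 2.0  # Poisson mean of comorbidity count
    p_wrong_site: float = 0.02  # planted error rate
    p_error_same_part: float = 0.75  # errors: flip side vs. distant body part
    p_unspecified_side: float = 0.06
    p_no_laterality: float = 0.10
    p_general_justification: float = 0.12
    p_proximity_pair: float = 0.02
    p_lateralized_comorbidity: float = 0.05  # comorbidity is a lateralized site code
    p_second_procedure: float = 0.10  # concurrent procedure at a proximate part
    p_infusion_only: float = 0.01  # claims whose only procedure is an infusion insertion
    p_other_specialty: float = 0.02  # claims billed under a different specialty
    n_comorbidity_codes: int = 8
    general_cluster_size: int = 4  # body parts sharing one general diagnosis code
    specialty_code: str = "20"  # CMS attending-specialty code for orthopedic surgery
    other_specialty_code: str = "99"
    year: int = 2020
    seed: int = 20170101

    def __post_init__(self) -> None:
        probs = {
            "p_wrong_site": self.p_wrong_site,
            "p_error_same_part": self.p_error_same_part,
            "p_unspecified_side": self.p_unspecified_side,
            "p_no_laterality": self.p_no_laterality,
            "p_general_justification": self.p_general_justification,
            "p_proximity_pair": self.p_proximity_pair,
            "p_lateralized_comorbidity": self.p_lateralized_comorbidity,
            "p_second_procedure": self.p_second_procedure,
            "p_infusion_only": self.p_infusion_only,
            "p_other_specialty": self.p_other_specialty,
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")
        if self.n_claims < 1:
            raise ValueError("n_claims must be >= 1")
        if not 1 <= self.n_body_parts <= len(_PART_CHARS):
            raise ValueError(f"n_body_parts must be in [1, {len(_PART_CHARS)}]")
        if self.p_proximity_pair > 0 and self.n_body_parts < 2:
            raise ValueError("proximity diagnoses need at least 2 body parts")
        if self.p_second_procedure > 0 and self.n_body_parts < 2:
            raise ValueError("concurrent procedures need at least 2 body parts")
        if self.p_wrong_site > 0 and self.p_error_same_part < 1 and self.n_body_parts < 4:
            raise ValueError("different-body-part errors need at least 4 body parts")
        if self.p_unspecified_side + self.p_no_laterality > 1:
            raise ValueError("p_unspecified_side + p_no_laterality exceeds 1")
        if self.p_general_justification + self.p_proximity_pair > 1:
            raise ValueError("p_general_justification + p_proximity_pair exceeds 1")


# ---------------------------------------------------------------------------
# Code universe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticUniverse:
    """The synthetic code grammar realized as concrete code tables + a CodeMap."""

    n_body_parts: int
    parts: tuple[str, ...]
    code_map: CodeMap = field(repr=False)
    general_cluster_size: int

    def part_id(self, index: int) -> str:
        return self.parts[index]

    def proc_code(self, part: int, side: int) -> str:
        return f"0S{_PART_CHARS[part]}{_SIDE_CHAR[side]}0ZZ"

    def infusion_code(self, side: int) -> str:
        return f"0VH{_SIDE_CHAR[side]}33Z"

    def diag_lateral(self, part: int, side: int) -> str:
        return f"M{part:02d}{_SIDE_DIGIT[side]}"

    def diag_unspecified(self, part: int) -> str:
        return f"M{part:02d}9"

    def diag_no_laterality(self, part: int) -> str:
        return f"Z{part:02d}0"

    def general_code(self, part: int) -> str:
        return f"G{part // self.general_cluster_size:02d}0"

    def comorbidity_code(self, k: int) -> str:
        return f"I{k:02d}9"

    def neighbors(self, part: int) -> tuple[int, ...]:
        out = []
        if part > 0:
            out.append(part - 1)
        if part < self.n_body_parts - 1:
            out.append(part + 1)
        return tuple(out)


def build_code_universe(config: GeneratorConfig) -> SyntheticUniverse:
    """Construct the code universe for a config (deterministic: grammar only)."""
    n = config.n_body_parts
    parts = tuple(f"part{i:02d}" for i in range(n))
    entries: dict[tuple[System, str], CodeMeta] = {}

    def add(system: System, code: str, **kwargs) -> None:
        entries[(system, code)] = CodeMeta(code=code, system=system, **kwargs)

    universe = SyntheticUniverse(
        n_body_parts=n,
        parts=parts,
        code_map=CodeMap({}),  # placeholder, replaced below
        general_cluster_size=config.general_cluster_size,
    )
    for i, part in enumerate(parts):
        for side in (0, 1):
            add(System.PCS, universe.proc_code(i, side), body_part=part, laterality=_SIDE_LAT[side])
            add(System.CM, universe.diag_lateral(i, side), body_part=part, laterality=_SIDE_LAT[side])
        add(System.CM, universe.diag_unspecified(i), body_part=part,
            laterality=Laterality.UNSPECIFIED_SIDE)
        add(System.CM, universe.diag_no_laterality(i), body_part=part,
            laterality=Laterality.NO_LATERALITY)
    for side in (0, 1):
        add(System.PCS, universe.infusion_code(side), body_part="infusion_site",
            laterality=_SIDE_LAT[side], is_infusion_device_insertion=True)
    n_clusters = (n + config.general_cluster_size - 1) // config.general_cluster_size
    for c in range(n_clusters):
        add(System.CM, f"G{c:02d}0", is_general=True)
    for k in range(config.n_comorbidity_codes):
        add(System.CM, universe.comorbidity_code(k))

    proximity = [(parts[i], parts[i + 1]) for i in range(n - 1)]
    code_map = CodeMap(entries, proximity)
    return replace(universe, code_map=code_map)


# ---------------------------------------------------------------------------
# Claim simulation
# ---------------------------------------------------------------------------

def simulate_claims(config: GeneratorConfig, universe: SyntheticUniverse) -> ClaimSet:
    """Sample a fully annotated corpus; byte-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_claims

    u_special = rng.random(n)
    part = rng.integers(0, config.n_body_parts, n)
    side = rng.integers(0, 2, n)
    u_path = rng.random(n)
    u_noise = rng.random(n)
    u_err = rng.random(n)
    u_errkind = rng.random(n)
    u_far = rng.random(n)
    u_neighbor = rng.random(n)
    u_second = rng.random(n)
    n_com = rng.poisson(config.mean_extra_diagnoses, n)

    total_com = int(n_com.sum()) + n  # headroom for forced comorbidities
    u_com_lat = rng.random(total_com)
    com_part = rng.integers(0, config.n_body_parts, total_com)
    com_side = rng.integers(0, 2, total_com)
    com_pool = rng.integers(0, max(config.n_comorbidity_codes, 1), total_com)

    pg = config.p_general_justification
    pp = config.p_proximity_pair
    pu = config.p_unspecified_side
    pn = config.p_no_laterality
    far_span = config.n_body_parts - 3  # offsets 2 .. n_parts-2 keep chain distance >= 2

    claims: list[CodedClaim] = []
    cursor = 0
    for i in range(n):
        p, s = int(part[i]), int(side[i])
        claim_id = f"C{i:07d}"

        # comorbidities (shared across claim types)
        k = int(n_com[i])
        comorbids: list[str] = []
        for j in range(cursor, cursor + k):
            if u_com_lat[j] < config.p_lateralized_comorbidity:
                comorbids.append(universe.diag_lateral(int(com_part[j]), int(com_side[j])))
            else:
                comorbids.append(universe.comorbidity_code(int(com_pool[j])))
        cursor += k

        if u_special[i] < config.p_infusion_only:
            if not comorbids:  # claims must carry >= 1 diagnosis
                comorbids = [universe.comorbidity_code(int(com_pool[cursor]))]
                cursor += 1
            claims.append(
                CodedClaim(
                    claim_id=claim_id,
                    year=config.year,
                    specialty_code=config.specialty_code,
                    procedure_codes=(universe.infusion_code(s),),
                    diagnosis_codes=tuple(comorbids),
                    truth=GroundTruth(is_error=False),
                )
            )
            continue

        specialty = config.specialty_code
        if u_special[i] < config.p_infusion_only + config.p_other_specialty:
            specialty = config.other_specialty_code

        # justifying diagnosis
        if u_path[i] < pg:
            justifying = universe.general_code(p)
            main_kind = NonErrorKind.GENERAL_DIAGNOSIS
        elif u_path[i] < pg + pp:
            nbrs = universe.neighbors(p)
            q = nbrs[int(u_neighbor[i] * len(nbrs))]
            justifying = universe.diag_lateral(q, s)
            main_kind = NonErrorKind.PROXIMITY
        elif u_noise[i] < pu:
            justifying = universe.diag_unspecified(p)
            main_kind = NonErrorKind.UNSPECIFIED_SIDE
        elif u_noise[i] < pu + pn:
            justifying = universe.diag_no_laterality(p)
            main_kind = NonErrorKind.NO_LATERALITY
        else:
            justifying = universe.diag_lateral(p, s)
            main_kind = NonErrorKind.NONE

        # main procedure, possibly corrupted
        is_error = u_err[i] < config.p_wrong_site
        if is_error:
            if u_errkind[i] < config.p_error_same_part:
                procedures = [universe.proc_code(p, 1 - s)]
                error_kind = ErrorKind.SAME_BODY_PART
            else:
                offset = 2 + int(u_far[i] * max(far_span, 1))
                far = (p + offset) % config.n_body_parts
                procedures = [universe.proc_code(far, 1 - s)]
                error_kind = ErrorKind.DIFFERENT_BODY_PART
        else:
            procedures = [universe.proc_code(p, s)]
            error_kind = ErrorKind.NONE

        # concurrent procedure at a proximate part, same side as the condition
        second_kind = NonErrorKind.NONE
        if (
            main_kind in (NonErrorKind.NONE, NonErrorKind.UNSPECIFIED_SIDE, NonErrorKind.NO_LATERALITY)
            and u_second[i] < config.p_second_procedure
        ):
            nbrs = universe.neighbors(p)
            q = nbrs[int(u_neighbor[i] * len(nbrs))]
            procedures.append(universe.proc_code(q, s))
            second_kind = (
                NonErrorKind.PROXIMITY if main_kind is NonErrorKind.NONE else NonErrorKind.COMBINATION
            )

        if is_error:
            truth = GroundTruth(True, error_kind, NonErrorKind.NONE, 0)
        else:
            claim_kind = max(main_kind, second_kind, key=NONERROR_PRIORITY.index)
            truth = GroundTruth(False, ErrorKind.NONE, claim_kind, 0)

        claims.append(
            CodedClaim(
                claim_id=claim_id,
                year=config.year,
                specialty_code=specialty,
                procedure_codes=tuple(procedures),
                diagnosis_codes=tuple([justifying] + comorbids),
                truth=truth,
            )
        )

    return ClaimSet(claims, provenance=f"synthetic(seed={config.seed}, n={n})")


def truth_summary(claims: ClaimSet, code_map: Optional[CodeMap] = None) -> pd.DataFrame:
    """Exact truth counts by (subgroup, is_error, error_kind, nonerror_kind).

    The subgroup column requires a code map; without one, counts are grouped
    over the truth fields only.  Raises if any claim lacks a truth record.
    """
    from lateraleye.laterality import assign_subgroup

    rows = []
    for claim in claims:
        if claim.truth is None:
            raise ValueError(f"claim {claim.claim_id} carries no ground truth")
        row = {
            "is_error": claim.truth.is_error,
            "error_kind": claim.truth.error_kind.value,
            "nonerror_kind": claim.truth.nonerror_kind.value,
        }
        if code_map is not None:
            row["subgroup"] = assign_subgroup(claim, code_map).value
        rows.append(row)
    frame = pd.DataFrame(rows)
    keys = [c for c in ("subgroup", "is_error", "error_kind", "nonerror_kind") if c in frame.columns]
    out = frame.groupby(keys, sort=True).size().rename("count").reset_index()
    return out
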