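"""Core claim data types, claim-table I/O, and the code-metadata mapping.

A *claim* is one inpatient billing record: an opaque identifier, a calendar
year, the attending physician's specialty code, an ordered list of ICD-10-PCS
procedure codes (7 characters) and an ordered list of ICD-10-CM diagnosis
codes (3-7 alphanumeric characters).  Synthetic claims additionally carry a
:class:`~lateraleye.synthetic_data.GroundTruth` annotation.

Laterality and body-part semantics of the codes are not hard-coded: they are
resolved through a :class:`CodeMap`, a longest-prefix-wins lookup from code
strings to :class:`CodeMeta`.  Real ICD-10-PCS encodes side inside the
body-part character (character 4) in a family-dependent way, and ICD-10-CM
encodes side in family-specific positions, so a prefix map is the only
mechanism that works uniformly for both systems.  A small default map
covering common orthopedic code families ships with the package; unknown
codes resolve to a neutral "general" record with a logged warning, because
claims data always contain codes outside any dictionary.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "System",
    "Laterality",
    "CodeMeta",
    "CodeMap",
    "CodedClaim",
    "ClaimSet",
    "SchemaError",
    "RowError",
    "ClaimValidationError",
    "CodeMapError",
    "read_claims",
    "write_claims",
    "load_code_map",
    "load_default_code_map",
]

LIST_DELIMITER = "|"
REQUIRED_COLUMNS = ("claim_id", "year", "specialty_code", "procedure_codes", "diagnosis_codes")


class System(str, Enum):
    """Coding system of a code string."""

    PCS = "PCS"  # ICD-10-PCS procedure codes
    CM = "CM"  # ICD-10-CM diagnosis codes


class Laterality(str, Enum):
    """Side information carried by a single code.

    ``UNSPECIFIED_SIDE`` means the code names a sided body part but documents
    the side as unspecified (e.g. "rotator cuff tear of unspecified
    shoulder"); ``NO_LATERALITY`` means the code carries no side dimension at
    all (either no body part, or a body part without a side).
    """

    LEFT = "LEFT"
    RIGHT = "RIGHT"
    BILATERAL = "BILATERAL"
    UNSPECIFIED_SIDE = "UNSPECIFIED_SIDE"
    NO_LATERALITY = "NO_LATERALITY"


SIDED = frozenset({Laterality.LEFT, Laterality.RIGHT, Laterality.BILATERAL})


class SchemaError(ValueError):
    """A required column is missing from a claim table."""


@dataclass(frozen=True)
class RowError:
    """A located validation failure for one input row."""

    row_index: int
    claim_id: Optional[str]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"row {self.row_index} (claim_id={self.claim_id!r}): {self.message}"


class ClaimValidationError(ValueError):
    """Raised when one or more claim rows fail validation; carries all of them."""

    def __init__(self, row_errors: Sequence[RowError]):
        self.row_errors = list(row_errors)
        lines = "\n".join(str(e) for e in self.row_errors[:20])
        more = "" if len(self.row_errors) <= 20 else f"\n... and {len(self.row_errors) - 20} more"
        super().__init__(f"{len(self.row_errors)} invalid claim row(s):\n{lines}{more}")


class CodeMapError(ValueError):
    """Raised for an internally inconsistent code map."""


@dataclass(frozen=True)
class CodeMeta:
    """Resolved metadata for one code (or code prefix).

    ``is_general`` marks a diagnosis that can justify a procedure without
    naming a body part (gangrene justifying an amputation, bone metastasis
    justifying bone surgery).  Codes with no body part that are *not* general
    (hypertension, nicotine dependence) justify nothing.
    """

    code: str
    system: System
    body_part: Optional[str] = None
    laterality: Laterality = Laterality.NO_LATERALITY
    is_general: bool = False
    is_infusion_device_insertion: bool = False

    def __post_init__(self) -> None:
        if self.laterality in SIDED and self.body_part is None:
            raise CodeMapError(
                f"{self.code}: laterality {self.laterality.value} requires a body part"
            )
        if self.is_general and (
            self.body_part is not None or self.laterality is not Laterality.NO_LATERALITY
        ):
            raise CodeMapError(f"{self.code}: a general diagnosis has no body part or side")
        if self.is_infusion_device_insertion and self.system is not System.PCS:
            raise CodeMapError(f"{self.code}: infusion-device insertion applies to PCS only")

    @property
    def is_lateralized(self) -> bool:
        return self.laterality in SIDED


def _unknown_meta(code: str, system: System) -> CodeMeta:
    # Unknown codes are treated as non-informative but potentially justifying:
    # a dictionary can never cover all of ICD-10, and flagging on ignorance
    # would swamp any review queue with false alarms.
    return CodeMeta(code=code, system=system, body_part=None,
                    laterality=Laterality.NO_LATERALITY,
                    is_general=(system is System.CM))


class CodeMap:
    """Longest-prefix-wins lookup from code strings to :class:`CodeMeta`.

    Parameters
    ----------
    entries
        Mapping ``(system, prefix) -> CodeMeta``.  Prefixes are unique per
        system, so resolution is deterministic.
    proximity
        Symmetric, irreflexive relation over *canonical sites* (see
        ``site_aliases``): pairs of anatomical areas considered adjacent,
        e.g. shoulder and humerus.
    site_aliases
        Optional mapping from fine body-part identifiers to canonical sites
        (``knee_joint -> knee``).  Identity where absent.
    """

    def __init__(
        self,
        entries: Mapping[tuple[System, str], CodeMeta],
        proximity: Iterable[tuple[str, str]] = (),
        site_aliases: Optional[Mapping[str, str]] = None,
    ):
        self._entries: dict[tuple[System, str], CodeMeta] = dict(entries)
        self._site_aliases: dict[str, str] = dict(site_aliases or {})
        self._prefixes_by_system: dict[System, list[str]] = {}
        for (system, prefix) in self._entries:
            self._prefixes_by_system.setdefault(system, []).append(prefix)
        pairs: set[frozenset[str]] = set()
        for a, b in proximity:
            if a == b:
                raise CodeMapError(f"proximity relation is irreflexive; got ({a}, {b})")
            pairs.add(frozenset((a, b)))
        self._proximity = pairs
        self._warned: set[str] = set()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_rows(
        cls,
        rows: Iterable[Mapping[str, str]],
        proximity_pairs: Iterable[tuple[str, str]] = (),
        site_aliases: Optional[Mapping[str, str]] = None,
    ) -> "CodeMap":
        entries: dict[tuple[System, str], CodeMeta] = {}
        for row in rows:
            prefix = str(row["code_or_prefix"]).strip()
            system = System(str(row["system"]).strip().upper())
            body_part = str(row.get("body_part", "") or "").strip() or None
            meta = CodeMeta(
                code=prefix,
                system=system,
                body_part=body_part,
                laterality=Laterality(str(row.get("laterality", "NO_LATERALITY")).strip().upper()),
                is_general=_parse_bool(row.get("is_general", False)),
                is_infusion_device_insertion=_parse_bool(
                    row.get("is_infusion_device_insertion", False)
                ),
            )
            key = (system, prefix)
            if key in entries:
                if entries[key] != meta:
                    raise CodeMapError(f"conflicting duplicate prefix {prefix!r} for {system.value}")
                continue
            entries[key] = meta
        return cls(entries, proximity_pairs, site_aliases)

    def with_entries(self, extra: Mapping[tuple[System, str], CodeMeta]) -> "CodeMap":
        merged = dict(self._entries)
        for key, meta in extra.items():
            if key in merged and merged[key] != meta:
                raise CodeMapError(f"conflicting duplicate prefix {key[1]!r} for {key[0].value}")
            merged[key] = meta
        return CodeMap(merged, [tuple(sorted(p)) for p in self._proximity], self._site_aliases)

    # -- resolution -------------------------------------------------------
    def resolve(self, code: str, system: System) -> CodeMeta:
        """Resolve ``code`` to metadata; total (unknown codes fall back)."""
        best: Optional[str] = None
        for prefix in self._prefixes_by_system.get(system, ()):
            if code.startswith(prefix) and (best is None or len(prefix) > len(best)):
                best = prefix
        if best is None:
            if code not in self._warned:
                self._warned.add(code)
                logger.warning("code %s (%s) not in code map; treated as general", code, system.value)
            return _unknown_meta(code, system)
        return replace(self._entries[(system, best)], code=code)

    def site(self, body_part: Optional[str]) -> Optional[str]:
        if body_part is None:
            return None
        return self._site_aliases.get(body_part, body_part)

    def proximate(self, part_a: Optional[str], part_b: Optional[str]) -> bool:
        """True when the two body parts map to proximate canonical sites."""
        sa, sb = self.site(part_a), self.site(part_b)
        if sa is None or sb is None or sa == sb:
            return False
        return frozenset((sa, sb)) in self._proximity

    @property
    def proximity_pairs(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(p)) for p in self._proximity)

    @property
    def entries(self) -> Mapping[tuple[System, str], CodeMeta]:
        return dict(self._entries)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"1", "true", "t", "yes", "y"}


# ---------------------------------------------------------------------------
# Claims
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodedClaim:
    """One claim: identifiers plus the procedure and diagnosis code lists."""

    claim_id: str
    year: int
    specialty_code: str
    procedure_codes: tuple[str, ...]
    diagnosis_codes: tuple[str, ...]
    truth: Optional["GroundTruth"] = None  # noqa: F821 - synthetic_data type

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if not self.claim_id:
            problems.append("empty claim_id")
        if not self.procedure_codes:
            problems.append("no procedure codes")
        if not self.diagnosis_codes:
            problems.append("no diagnosis codes")
        for code in self.procedure_codes:
            if len(code) != 7 or not code.isalnum():
                problems.append(f"PCS code {code!r} is not a 7-character alphanumeric string")
        for code in self.diagnosis_codes:
            if not (3 <= len(code) <= 7) or not code.isalnum() or not code[0].isalpha():
                problems.append(
                    f"CM code {code!r} must be 3-7 alphanumeric characters starting with a letter"
                )
        return problems


@dataclass
class ClaimSet:
    """A validated collection of claims with set-wide unique claim ids."""

    claims: list[CodedClaim] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.claims)

    def __iter__(self):
        return iter(self.claims)

    def validate(self) -> None:
        errors: list[RowError] = []
        seen: dict[str, int] = {}
        for i, claim in enumerate(self.claims):
            for problem in claim.validate():
                errors.append(RowError(i, claim.claim_id, problem))
            if claim.claim_id in seen:
                errors.append(
                    RowError(i, claim.claim_id, f"duplicate claim_id (first at row {seen[claim.claim_id]})")
                )
            else:
                seen[claim.claim_id] = i
        if errors:
            raise ClaimValidationError(errors)


# ---------------------------------------------------------------------------
# Claim-table I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "parquet" if path.suffix.lower() in {".parquet", ".pq"} else "csv"


def _truth_to_json(truth) -> Optional[str]:
    if truth is None:
        return None
    return json.dumps(truth.to_dict(), sort_keys=True)


def _truth_from_json(text) -> Optional["GroundTruth"]:  # noqa: F821
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return None
    from lateraleye.synthetic_data import GroundTruth

    return GroundTruth.from_dict(json.loads(text))


def write_claims(claims: ClaimSet, path, fmt: Optional[str] = None) -> Path:
    """Write a claim table; list columns are pipe-delimited in CSV, native in Parquet."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records = {
        "claim_id": [c.claim_id for c in claims],
        "year": [c.year for c in claims],
        "specialty_code": [c.specialty_code for c in claims],
        "procedure_codes": [list(c.procedure_codes) for c in claims],
        "diagnosis_codes": [list(c.diagnosis_codes) for c in claims],
        "truth_json": [_truth_to_json(c.truth) for c in claims],
    }
    frame = pd.DataFrame(records, columns=list(records))
    if fmt == "csv":
        frame = frame.copy()
        frame["procedure_codes"] = [LIST_DELIMITER.join(v) for v in frame["procedure_codes"]]
        frame["diagnosis_codes"] = [LIST_DELIMITER.join(v) for v in frame["diagnosis_codes"]]
        frame.to_csv(path, index=False)
    elif fmt == "parquet":
        frame.to_parquet(path, index=False)
    else:
        raise ValueError(f"unknown claim-table format {fmt!r}")
    return path


def read_claims(path, fmt: Optional[str] = None, errors: str = "raise") -> ClaimSet:
    """Read and validate a claim table.

    With ``errors="raise"`` (default) any malformed row aborts the read with a
    :class:`ClaimValidationError` listing *all* offending rows.  With
    ``errors="collect"`` the return value is ``(ClaimSet, [RowError, ...])``
    and well-formed rows are kept; accepted + rejected always equals the
    number of input rows.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        frame = pd.read_csv(
            path,
            dtype={
                "claim_id": str,
                "specialty_code": str,
                "truth_json": str,
                "procedure_codes": str,
                "diagnosis_codes": str,
            },
        )
    elif fmt == "parquet":
        frame = pd.read_parquet(path)
    else:
        raise ValueError(f"unknown claim-table format {fmt!r}")

    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"claim table {path} is missing required column(s): {', '.join(missing)}")
    if "truth_json" not in frame.columns:
        frame["truth_json"] = None

    accepted: list[CodedClaim] = []
    row_errors: list[RowError] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        claim_id = str(row.claim_id)
        try:
            claim = CodedClaim(
                claim_id=claim_id,
                year=int(row.year),
                specialty_code=str(row.specialty_code),
                procedure_codes=_as_code_tuple(row.procedure_codes),
                diagnosis_codes=_as_code_tuple(row.diagnosis_codes),
                truth=_truth_from_json(row.truth_json),
            )
        except (ValueError, TypeError, KeyError) as exc:
            row_errors.append(RowError(i, claim_id, f"unparseable row: {exc}"))
            continue
        problems = claim.validate()
        if claim_id in seen:
            problems.append(f"duplicate claim_id (first at row {seen[claim_id]})")
        else:
            seen[claim_id] = i
        if problems:
            row_errors.extend(RowError(i, claim_id, p) for p in problems)
        else:
            accepted.append(claim)

    claim_set = ClaimSet(accepted, provenance=str(path))
    if errors == "collect":
        return claim_set, row_errors
    if row_errors:
        raise ClaimValidationError(row_errors)
    return claim_set


def _as_code_tuple(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ()
    if isinstance(value, str):
        return tuple(part for part in value.split(LIST_DELIMITER) if part)
    return tuple(str(v) for v in value)


# ---------------------------------------------------------------------------
# Code-map I/O
# ---------------------------------------------------------------------------

def load_code_map(
    map_path,
    proximity_path=None,
    site_alias_path=None,
) -> CodeMap:
    """Load a code map from CSV files.

    ``map_path`` columns: code_or_prefix, system, body_part, laterality,
    is_general, is_infusion_device_insertion.  ``proximity_path`` columns:
    body_part_a, body_part_b (each unordered pair listed once; reflexive
    pairs are rejected).  ``site_alias_path`` columns: body_part, site.
    """
    with open(map_path, newline="") as handle:
        rows = list(csv.DictReader(handle))
    proximity: list[tuple[str, str]] = []
    if proximity_path is not None:
        with open(proximity_path, newline="") as handle:
            for row in csv.DictReader(handle):
                proximity.append((row["body_part_a"].strip(), row["body_part_b"].strip()))
    aliases: dict[str, str] = {}
    if site_alias_path is not None:
        with open(site_alias_path, newline="") as handle:
            for row in csv.DictReader(handle):
                aliases[row["body_part"].strip()] = row["site"].strip()
    return CodeMap.from_rows(rows, proximity, aliases)


def load_default_code_map() -> CodeMap:
    """The packaged default map: common orthopedic code families plus a
    shoulder/humerus-style proximity relation.  Extensible, not exhaustive."""
    data = resources.files("lateraleye") / "data"
    with resources.as_file(data / "default_code_map.csv") as m, resources.as_file(
        data / "default_proximity.csv"
    ) as p, resources.as_file(data / "default_site_aliases.csv") as s:
        return load_code_map(m, p, s)
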