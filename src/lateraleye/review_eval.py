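"""Deterministic clinical-review engine and the rule-vs-model comparison.

``auto_review`` re-implements, as a rule engine over the code map, the
review criteria a clinician applies to a flagged claim: a procedure is
justified if some diagnosis names the same anatomical site with a matching
side; failing that, if a same-site diagnosis documents an unspecified side,
or a site without laterality; failing that, if a general diagnosis
(gangrene, metastasis, device complication) can explain the surgery; failing
that, if a lateralized diagnosis names a *proximate* site on the compatible
side; and finally, one level deep, if a concurrent procedure at the same or
a proximate site on the same side is itself directly justified
(combination).  A claim is a confirmed error when any procedure remains
unjustified; the error is classified by whether some diagnosis names the
same site on the opposite side (same body part) or not (different body
part).  A nonerror claim is labeled with the weakest justification used
among its procedures — that rationale is what made it survive review.

``compare_methods`` assembles the per-subgroup contingency table (flagged
counts, confirmed error/nonerror subcategory breakdowns, per-method and
pooled precision) for the rule-based method (which flags every
discordant-laterality claim) and the association model (which flags claims
scoring below the operating threshold).  ``suppress_small_cells`` applies
the disclosure rule that masks any displayed cell with a count of 10 or
fewer (zero cells carry no disclosure risk and are shown).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

from lateraleye.aop_model import AssociationTable, PRPoint, Threshold, score_claim
from lateraleye.claims_model import ClaimSet, CodeMap, CodedClaim, Laterality, System
from lateraleye.laterality import DISCORDANT, Subgroup, assign_subgroup
from lateraleye.synthetic_data import NONERROR_PRIORITY, ErrorKind, NonErrorKind

__all__ = [
    "ReviewLabel",
    "MethodCell",
    "ComparisonReport",
    "auto_review",
    "compare_methods",
    "suppress_small_cells",
    "render_report",
]

_ERROR_KIND_ORDER = (ErrorKind.SAME_BODY_PART, ErrorKind.DIFFERENT_BODY_PART)
_NONERROR_KIND_ORDER = (
    NonErrorKind.UNSPECIFIED_SIDE,
    NonErrorKind.NO_LATERALITY,
    NonErrorKind.GENERAL_DIAGNOSIS,
    NonErrorKind.PROXIMITY,
    NonErrorKind.COMBINATION,
    NonErrorKind.NONE,
)


@dataclass(frozen=True)
class ReviewLabel:
    is_error: bool
    error_kind: ErrorKind = ErrorKind.NONE
    nonerror_kind: NonErrorKind = NonErrorKind.NONE
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.is_error and (
            self.error_kind is ErrorKind.NONE or self.nonerror_kind is not NonErrorKind.NONE
        ):
            raise ValueError("error labels need an error kind and no nonerror kind")
        if not self.is_error and self.error_kind is not ErrorKind.NONE:
            raise ValueError("nonerror labels cannot carry an error kind")


def _side_compatible(diag: Laterality, proc: Laterality) -> bool:
    if diag is Laterality.BILATERAL or proc is Laterality.BILATERAL:
        return True
    return diag is proc


def auto_review(claim: CodedClaim, code_map: CodeMap) -> ReviewLabel:
    """Apply the review criteria to one claim (deterministic, total)."""
    diag = [(c, code_map.resolve(c, System.CM)) for c in claim.diagnosis_codes]
    procs = [(c, code_map.resolve(c, System.PCS)) for c in claim.procedure_codes]

    kinds: list[Optional[NonErrorKind]] = []  # None = unjustified (so far)
    rationale: list[str] = []
    same_part_evidence: list[bool] = []

    for p_code, p_meta in procs:
        p_site = code_map.site(p_meta.body_part)
        if p_site is None or not p_meta.is_lateralized or p_meta.is_infusion_device_insertion:
            # No site/side to contradict (or an infusion insertion, whose
            # site rationale is clinician-determined): not reviewable.
            kinds.append(NonErrorKind.NONE)
            rationale.append(f"{p_code}: no reviewable site/side")
            same_part_evidence.append(False)
            continue
        found: Optional[NonErrorKind] = None
        via: str = ""
        opposite_same_site = False
        for d_code, d_meta in diag:
            d_site = code_map.site(d_meta.body_part)
            if d_site == p_site and d_meta.is_lateralized:
                if _side_compatible(d_meta.laterality, p_meta.laterality):
                    found, via = NonErrorKind.NONE, d_code
                    break
                opposite_same_site = True
        if found is None:
            for kind, predicate in (
                (
                    NonErrorKind.UNSPECIFIED_SIDE,
                    lambda d: code_map.site(d.body_part) == p_site
                    and d.laterality is Laterality.UNSPECIFIED_SIDE,
                ),
                (
                    NonErrorKind.NO_LATERALITY,
                    lambda d: d.body_part is not None
                    and code_map.site(d.body_part) == p_site
                    and d.laterality is Laterality.NO_LATERALITY,
                ),
                (NonErrorKind.GENERAL_DIAGNOSIS, lambda d: d.is_general),
                (
                    NonErrorKind.PROXIMITY,
                    lambda d: d.is_lateralized
                    and code_map.proximate(d.body_part, p_meta.body_part)
                    and _side_compatible(d.laterality, p_meta.laterality),
                ),
            ):
                for d_code, d_meta in diag:
                    if predicate(d_meta):
                        found, via = kind, d_code
                        break
                if found is not None:
                    break
        kinds.append(found)
        rationale.append(
            f"{p_code}: justified by {via} ({found.value})" if found is not None
            else f"{p_code}: unjustified"
        )
        same_part_evidence.append(opposite_same_site)

    # Combination pass (one level deep): an unjustified procedure may ride on
    # a directly justified concurrent procedure at the same/proximate site
    # and the same side.
    for i, (p_code, p_meta) in enumerate(procs):
        if kinds[i] is not None:
            continue
        p_site = code_map.site(p_meta.body_part)
        for j, (q_code, q_meta) in enumerate(procs):
            if i == j or kinds[j] is None:
                continue
            q_site = code_map.site(q_meta.body_part)
            if q_site is None:
                continue
            same_or_near = q_site == p_site or code_map.proximate(
                p_meta.body_part, q_meta.body_part
            )
            if same_or_near and _side_compatible(q_meta.laterality, p_meta.laterality):
                kinds[i] = NonErrorKind.COMBINATION
                rationale[i] = f"{p_code}: justified via concurrent procedure {q_code} (COMBINATION)"
                break

    if any(kind is None for kind in kinds):
        same = any(ev for kind, ev in zip(kinds, same_part_evidence) if kind is None)
        return ReviewLabel(
            is_error=True,
            error_kind=ErrorKind.SAME_BODY_PART if same else ErrorKind.DIFFERENT_BODY_PART,
            rationale=tuple(rationale),
        )
    claim_kind = max(kinds, key=NONERROR_PRIORITY.index)
    return ReviewLabel(is_error=False, nonerror_kind=claim_kind, rationale=tuple(rationale))


# ---------------------------------------------------------------------------
# Comparison report
# ---------------------------------------------------------------------------

@dataclass
class MethodCell:
    """One method x subgroup cell of the contingency table."""

    flagged: int = 0
    error_kinds: dict[str, int] = field(default_factory=dict)
    nonerror_kinds: dict[str, int] = field(default_factory=dict)

    @property
    def errors(self) -> int:
        return sum(self.error_kinds.values())

    @property
    def nonerrors(self) -> int:
        return sum(self.nonerror_kinds.values())

    @property
    def precision(self) -> Optional[float]:
        return None if self.flagged == 0 else self.errors / self.flagged

    def check_conservation(self) -> None:
        if self.errors + self.nonerrors != self.flagged:
            raise ValueError(
                f"cell inconsistency: {self.errors} errors + {self.nonerrors} nonerrors "
                f"!= {self.flagged} flagged"
            )


@dataclass
class ComparisonReport:
    """Per-method, per-subgroup contingency counts plus pooled precision."""

    cells: dict[tuple[str, str], MethodCell]  # (method, subgroup) -> cell
    label_source: str = "ground_truth"
    pr_points: list[PRPoint] = field(default_factory=list)
    masked: set[tuple[str, ...]] = field(default_factory=set)
    min_reportable: Optional[int] = None

    @property
    def methods(self) -> list[str]:
        return sorted({m for m, _ in self.cells})

    @property
    def subgroups(self) -> list[str]:
        return sorted({g for _, g in self.cells})

    def cell(self, method: str, subgroup: str) -> MethodCell:
        return self.cells[(method, subgroup)]

    def pooled_precision(self, method: str) -> Optional[float]:
        flagged = sum(c.flagged for (m, _), c in self.cells.items() if m == method)
        errors = sum(c.errors for (m, _), c in self.cells.items() if m == method)
        return None if flagged == 0 else errors / flagged

    def validate(self) -> None:
        for cell in self.cells.values():
            cell.check_conservation()

    @classmethod
    def from_counts(cls, counts: dict, label_source: str = "fixture") -> "ComparisonReport":
        """Build a report from a nested count dict:
        ``{method: {subgroup: {"error_kinds": {...}, "nonerror_kinds": {...}}}}``
        (an explicit ``"flagged"`` is cross-checked against the kind sums)."""
        cells: dict[tuple[str, str], MethodCell] = {}
        for method, by_group in counts.items():
            if method == "description":
                continue
            for subgroup, data in by_group.items():
                cell = MethodCell(
                    flagged=int(
                        data.get(
                            "flagged",
                            sum(data["error_kinds"].values()) + sum(data["nonerror_kinds"].values()),
                        )
                    ),
                    error_kinds={k: int(v) for k, v in data["error_kinds"].items()},
                    nonerror_kinds={k: int(v) for k, v in data["nonerror_kinds"].items()},
                )
                cell.check_conservation()
                cells[(method, subgroup)] = cell
        return cls(cells=cells, label_source=label_source)


def _label_for(claim: CodedClaim, code_map: CodeMap, source: str) -> ReviewLabel:
    if source == "auto_review":
        return auto_review(claim, code_map)
    if source == "ground_truth":
        if claim.truth is None:
            raise ValueError(f"claim {claim.claim_id} has no ground truth annotation")
        return ReviewLabel(
            is_error=claim.truth.is_error,
            error_kind=claim.truth.error_kind,
            nonerror_kind=claim.truth.nonerror_kind,
        )
    raise ValueError(f"unknown label source {source!r}")


def compare_methods(
    claims: ClaimSet,
    code_map: CodeMap,
    table: AssociationTable,
    threshold: Threshold,
    labels: str = "ground_truth",
    pr_points: Optional[Sequence[PRPoint]] = None,
) -> ComparisonReport:
    """Evaluate the rule-based flag and the association model on the two
    discordant-laterality subgroups (LR, RL) of ``claims``."""
    cells = {
        (method, group.value): MethodCell()
        for method in ("rule", "aop")
        for group in (Subgroup.LR, Subgroup.RL)
    }
    for claim in claims:
        subgroup = assign_subgroup(claim, code_map)
        if subgroup not in DISCORDANT:
            continue
        label = _label_for(claim, code_map, labels)
        aop_flagged = score_claim(claim, table, code_map, threshold).flagged
        for method, flagged in (("rule", True), ("aop", aop_flagged)):
            if not flagged:
                continue
            cell = cells[(method, subgroup.value)]
            cell.flagged += 1
            if label.is_error:
                k = label.error_kind.value
                cell.error_kinds[k] = cell.error_kinds.get(k, 0) + 1
            else:
                k = label.nonerror_kind.value
                cell.nonerror_kinds[k] = cell.nonerror_kinds.get(k, 0) + 1
    report = ComparisonReport(
        cells=cells, label_source=labels, pr_points=list(pr_points or [])
    )
    report.validate()
    return report


def suppress_small_cells(report: ComparisonReport, min_reportable: int = 11) -> ComparisonReport:
    """Flag every displayable cell with 0 < count < min_reportable for
    masking.  Counts are kept intact internally; masking is render-time."""
    masked: set[tuple[str, ...]] = set()

    def consider(count: int, *key: str) -> None:
        if 0 < count < min_reportable:
            masked.add(key)

    for (method, subgroup), cell in report.cells.items():
        consider(cell.flagged, method, subgroup, "flagged")
        consider(cell.errors, method, subgroup, "errors")
        consider(cell.nonerrors, method, subgroup, "nonerrors")
        for kind, count in cell.error_kinds.items():
            consider(count, method, subgroup, "error", kind)
        for kind, count in cell.nonerror_kinds.items():
            consider(count, method, subgroup, "nonerror", kind)
    return replace(report, masked=masked, min_reportable=min_reportable)


MASK_TOKEN = "suppressed"


def render_report(report: ComparisonReport, out_dir) -> Path:
    """Write comparison_report.csv, summary.txt and pr_points.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def shown(count: int, *key: str) -> str:
        return MASK_TOKEN if key in report.masked else str(count)

    rows: list[dict[str, str]] = []
    for (method, subgroup), cell in sorted(report.cells.items()):
        rows.append(
            {
                "method": method,
                "subgroup": subgroup,
                "category": "flagged",
                "kind": "",
                "count": shown(cell.flagged, method, subgroup, "flagged"),
            }
        )
        rows.append(
            {
                "method": method,
                "subgroup": subgroup,
                "category": "error",
                "kind": "TOTAL",
                "count": shown(cell.errors, method, subgroup, "errors"),
            }
        )
        for kind in _ERROR_KIND_ORDER:
            count = cell.error_kinds.get(kind.value, 0)
            rows.append(
                {
                    "method": method,
                    "subgroup": subgroup,
                    "category": "error",
                    "kind": kind.value,
                    "count": shown(count, method, subgroup, "error", kind.value),
                }
            )
        rows.append(
            {
                "method": method,
                "subgroup": subgroup,
                "category": "nonerror",
                "kind": "TOTAL",
                "count": shown(cell.nonerrors, method, subgroup, "nonerrors"),
            }
        )
        for kind in _NONERROR_KIND_ORDER:
            count = cell.nonerror_kinds.get(kind.value, 0)
            if kind is NonErrorKind.NONE and count == 0:
                continue
            rows.append(
                {
                    "method": method,
                    "subgroup": subgroup,
                    "category": "nonerror",
                    "kind": kind.value,
                    "count": shown(count, method, subgroup, "nonerror", kind.value),
                }
            )
    report_path = out_dir / "comparison_report.csv"
    with open(report_path, "w", newline="") as handle:
        writer = csv.DictWriter(handle, fieldnames=["method", "subgroup", "category", "kind", "count"])
        writer.writeheader()
        writer.writerows(rows)

    lines = [f"Method comparison (labels: {report.label_source})", ""]
    for method in report.methods:
        for subgroup in report.subgroups:
            cell = report.cell(method, subgroup)
            precision = cell.precision
            p_txt = "undefined" if precision is None else f"{100 * precision:.1f}%"
            lines.append(
                f"{method:>5s} {subgroup}: flagged={shown(cell.flagged, method, subgroup, 'flagged')} "
                f"errors={shown(cell.errors, method, subgroup, 'errors')} precision={p_txt}"
            )
        pooled = report.pooled_precision(method)
        pooled_txt = "undefined" if pooled is None else f"{100 * pooled:.1f}%"
        lines.append(f"{method:>5s} pooled precision: {pooled_txt}")
        lines.append("")
    (out_dir / "summary.txt").write_text("\n".join(lines))

    pr_path = out_dir / "pr_points.csv"
    with open(pr_path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["threshold", "precision", "recall", "flagged", "true_positives"])
        for pt in report.pr_points:
            writer.writerow([pt.threshold, pt.precision, pt.recall, pt.flagged, pt.true_positives])
    return report_path
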