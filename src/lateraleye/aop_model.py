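"""Association-outlier scoring of procedure-diagnosis substantiation.

The model learns, from a training corpus, how often each procedure key
co-occurs with each diagnosis key at claim level, and converts counts to a
score in [0, 1]:

``CONFIDENCE`` (default)
    The Laplace-smoothed probability that a procedure drawn from a claim
    containing diagnosis ``d`` is ``p``::

        s(p | d) = (c(p, d) + alpha) / (m(d) + alpha * |P|)

    where ``c(p, d)`` counts claims containing both keys, ``m(d) = sum_p
    c(p, d)`` is the diagnosis key's pair mass, and ``|P|`` is the number of
    distinct procedure keys at that level.  The smoothed scores over the
    procedure universe sum to one for every diagnosis key.

``LIFT``
    The smoothed observed/expected co-occurrence ratio mapped into (0, 1)::

        lambda = (c(p,d) + a)(n + a) / ((c(p) + a)(c(d) + a));  s = lambda / (1 + lambda)

    so independence gives s = 0.5 as alpha -> 0.

Counts are kept at three key resolutions: the full code, the code with its
side stripped (body part + laterality class), and the bare body part.  A
pair is scored at the finest level at which its diagnosis key was seen in
training; coarser levels exist so genuinely novel codes degrade gracefully
rather than defaulting to "unknown".  Keys unseen at every level score at
the smoothing floor and therefore flag at any operating threshold above it.

A claim is *substantiated* when every procedure has at least one diagnosis
with a high association: the per-procedure score is the maximum over the
claim's diagnoses, the claim score is the minimum over its procedures, and
the claim is flagged when the claim score falls strictly below the
operating threshold.  The max rule deliberately means a conflicting
diagnosis cannot un-substantiate a procedure that another diagnosis
justifies; that asymmetry is a known property of the approach, not a bug to
heuristically patch.  The operating threshold is read off the
precision-recall curve of a labeled calibration set, either at maximal F1
or as the highest-recall point meeting a precision floor.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from lateraleye.claims_model import ClaimSet, CodeMap, CodedClaim, System

__all__ = [
    "ScoreMode",
    "ThresholdRule",
    "AssociationTable",
    "ClaimScore",
    "PRPoint",
    "Threshold",
    "train_associations",
    "association_score",
    "score_claim",
    "score_claims",
    "precision_recall_points",
    "select_threshold",
]


class ScoreMode(str, Enum):
    CONFIDENCE = "CONFIDENCE"
    LIFT = "LIFT"


class ThresholdRule(str, Enum):
    MAX_F1 = "MAX_F1"
    PRECISION_FLOOR = "PRECISION_FLOOR"


#: Key-resolution levels, finest first.
BACKOFF_LEVELS = ("code", "side_stripped", "body_part")


def _key_at_level(code: str, meta, level: str) -> str:
    """Backoff key for a code.  Codes without a body part cannot be
    coarsened and keep their full code at every level."""
    if level == "code" or meta.body_part is None:
        return code
    if level == "side_stripped":
        lat = "SIDED" if meta.is_lateralized else meta.laterality.value
        return f"{meta.body_part}|{lat}"
    return meta.body_part


@dataclass
class _LevelCounts:
    pair_counts: Counter = field(default_factory=Counter)
    proc_marginals: Counter = field(default_factory=Counter)
    diag_marginals: Counter = field(default_factory=Counter)
    diag_pair_mass: Counter = field(default_factory=Counter)

    @property
    def n_procedure_keys(self) -> int:
        return len(self.proc_marginals)


@dataclass
class AssociationTable:
    """Trained co-occurrence counts at every backoff level."""

    levels: dict[str, _LevelCounts]
    n_claims_trained: int
    smoothing_alpha: float
    score_mode: ScoreMode
    backoff_levels: tuple[str, ...] = BACKOFF_LEVELS
    version: str = "1"

    # -- persistence ------------------------------------------------------
    def to_json(self, path) -> Path:
        payload = {
            "version": self.version,
            "n_claims_trained": self.n_claims_trained,
            "smoothing_alpha": self.smoothing_alpha,
            "score_mode": self.score_mode.value,
            "backoff_levels": list(self.backoff_levels),
            "levels": {
                name: {
                    "pair_counts": [[p, d, c] for (p, d), c in sorted(lvl.pair_counts.items())],
                    "proc_marginals": sorted(lvl.proc_marginals.items()),
                    "diag_marginals": sorted(lvl.diag_marginals.items()),
                }
                for name, lvl in self.levels.items()
            },
        }
        path = Path(path)
        path.write_text(json.dumps(payload, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path) -> "AssociationTable":
        payload = json.loads(Path(path).read_text())
        levels: dict[str, _LevelCounts] = {}
        for name, data in payload["levels"].items():
            lvl = _LevelCounts()
            for p, d, c in data["pair_counts"]:
                lvl.pair_counts[(p, d)] = c
                lvl.diag_pair_mass[d] += c
            lvl.proc_marginals.update(dict((k, v) for k, v in data["proc_marginals"]))
            lvl.diag_marginals.update(dict((k, v) for k, v in data["diag_marginals"]))
            levels[name] = lvl
        return cls(
            levels=levels,
            n_claims_trained=payload["n_claims_trained"],
            smoothing_alpha=payload["smoothing_alpha"],
            score_mode=ScoreMode(payload["score_mode"]),
            backoff_levels=tuple(payload["backoff_levels"]),
            version=str(payload.get("version", "1")),
        )


def train_associations(
    claims: ClaimSet,
    code_map: CodeMap,
    alpha: float = 1.0,
    mode: ScoreMode = ScoreMode.CONFIDENCE,
    backoff_levels: Sequence[str] = BACKOFF_LEVELS,
) -> AssociationTable:
    """Count claim-level procedure-diagnosis co-occurrence.

    Each (procedure key, diagnosis key) pair is counted once per claim
    regardless of how many code instances realize it; marginals count claims
    containing the key.
    """
    if len(claims) == 0:
        raise ValueError("cannot train associations on an empty claim set")
    if alpha <= 0:
        raise ValueError("smoothing_alpha must be positive")
    levels = {name: _LevelCounts() for name in backoff_levels}
    for claim in claims:
        proc_metas = [(c, code_map.resolve(c, System.PCS)) for c in claim.procedure_codes]
        diag_metas = [(c, code_map.resolve(c, System.CM)) for c in claim.diagnosis_codes]
        for name in backoff_levels:
            lvl = levels[name]
            p_keys = {_key_at_level(c, m, name) for c, m in proc_metas}
            d_keys = {_key_at_level(c, m, name) for c, m in diag_metas}
            for pk in p_keys:
                lvl.proc_marginals[pk] += 1
            for dk in d_keys:
                lvl.diag_marginals[dk] += 1
            for pk in p_keys:
                for dk in d_keys:
                    lvl.pair_counts[(pk, dk)] += 1
                    lvl.diag_pair_mass[dk] += 1
    return AssociationTable(
        levels=levels,
        n_claims_trained=len(claims),
        smoothing_alpha=alpha,
        score_mode=mode,
        backoff_levels=tuple(backoff_levels),
    )


def _score_at_level(table: AssociationTable, lvl: _LevelCounts, pk: str, dk: str) -> float:
    a = table.smoothing_alpha
    c_pd = lvl.pair_counts.get((pk, dk), 0)
    if table.score_mode is ScoreMode.CONFIDENCE:
        universe = max(lvl.n_procedure_keys, 1)
        return (c_pd + a) / (lvl.diag_pair_mass.get(dk, 0) + a * universe)
    n = table.n_claims_trained
    lam = ((c_pd + a) * (n + a)) / (
        (lvl.proc_marginals.get(pk, 0) + a) * (lvl.diag_marginals.get(dk, 0) + a)
    )
    return lam / (1.0 + lam)


def association_score(
    table: AssociationTable,
    code_map: CodeMap,
    procedure_code: str,
    diagnosis_code: str,
) -> float:
    """Score one procedure-diagnosis pair in [0, 1].

    The pair is scored at the finest backoff level at which the diagnosis
    key was seen in training; a diagnosis unseen at every level scores at
    the smoothing floor of the coarsest level.
    """
    p_meta = code_map.resolve(procedure_code, System.PCS)
    d_meta = code_map.resolve(diagnosis_code, System.CM)
    for name in table.backoff_levels:
        lvl = table.levels[name]
        dk = _key_at_level(diagnosis_code, d_meta, name)
        if lvl.diag_marginals.get(dk, 0) > 0:
            pk = _key_at_level(procedure_code, p_meta, name)
            return _score_at_level(table, lvl, pk, dk)
    coarsest = table.backoff_levels[-1]
    lvl = table.levels[coarsest]
    return _score_at_level(
        table,
        lvl,
        _key_at_level(procedure_code, p_meta, coarsest),
        _key_at_level(diagnosis_code, d_meta, coarsest),
    )


@dataclass(frozen=True)
class ClaimScore:
    claim_id: str
    per_procedure_scores: tuple[tuple[str, float, str], ...]  # (proc, max score, argmax diag)
    claim_score: float
    flagged: bool


@dataclass(frozen=True)
class Threshold:
    value: float
    selection_rule: ThresholdRule
    precision: float
    recall: float

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "value": self.value,
                    "selection_rule": self.selection_rule.value,
                    "precision": self.precision,
                    "recall": self.recall,
                },
                sort_keys=True,
            )
        )
        return path

    @classmethod
    def from_json(cls, path) -> "Threshold":
        data = json.loads(Path(path).read_text())
        return cls(
            value=data["value"],
            selection_rule=ThresholdRule(data["selection_rule"]),
            precision=data["precision"],
            recall=data["recall"],
        )


def score_claim(
    claim: CodedClaim,
    table: AssociationTable,
    code_map: CodeMap,
    threshold: Optional[Threshold] = None,
) -> ClaimScore:
    """min-over-procedures of max-over-diagnoses association.

    A claim is substantiated only if *every* procedure finds some diagnosis
    with a high association; the weakest procedure determines the claim.
    """
    per_proc: list[tuple[str, float, str]] = []
    diag_codes = list(dict.fromkeys(claim.diagnosis_codes))
    for proc in dict.fromkeys(claim.procedure_codes):
        best_score, best_diag = -1.0, ""
        for diag in diag_codes:
            s = association_score(table, code_map, proc, diag)
            if s > best_score:
                best_score, best_diag = s, diag
        per_proc.append((proc, best_score, best_diag))
    claim_score = min(s for _, s, _ in per_proc)
    flagged = threshold is not None and claim_score < threshold.value
    return ClaimScore(claim.claim_id, tuple(per_proc), claim_score, flagged)


def score_claims(
    claims: ClaimSet,
    table: AssociationTable,
    code_map: CodeMap,
    threshold: Optional[Threshold] = None,
) -> list[ClaimScore]:
    return [score_claim(c, table, code_map, threshold) for c in claims]


# ---------------------------------------------------------------------------
# Precision-recall and threshold selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float
    recall: float
    flagged: int
    true_positives: int


def precision_recall_points(
    scores: Sequence[Union[ClaimScore, float]],
    labels: Sequence[bool],
) -> list[PRPoint]:
    """Operating points of the flag "score < t" against error labels.

    Candidate thresholds are the distinct observed scores plus 1.0 (flag
    everything scoring below the top of the scale); thresholds that flag
    nothing are omitted because their precision is undefined.  Recall is
    nondecreasing in the threshold.
    """
    values = np.asarray(
        [s.claim_score if isinstance(s, ClaimScore) else float(s) for s in scores], dtype=float
    )
    y = np.asarray(labels, dtype=bool)
    if values.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("precision-recall needs at least one positive (error) label")

    order = np.argsort(values, kind="stable")
    sorted_scores = values[order]
    sorted_pos = y[order].astype(int)
    cum_pos = np.cumsum(sorted_pos)

    candidates = np.unique(values)
    if candidates.size == 0 or candidates[-1] < 1.0:
        candidates = np.append(candidates, 1.0)
    points: list[PRPoint] = []
    for t in candidates:
        flagged = int(np.searchsorted(sorted_scores, t, side="left"))
        if flagged == 0:
            continue
        tp = int(cum_pos[flagged - 1])
        points.append(
            PRPoint(
                threshold=float(t),
                precision=tp / flagged,
                recall=tp / n_pos,
                flagged=flagged,
                true_positives=tp,
            )
        )
    return points


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def select_threshold(
    points: Sequence[PRPoint],
    rule: ThresholdRule = ThresholdRule.MAX_F1,
    precision_floor: Optional[float] = None,
) -> Threshold:
    """Pick the operating point.

    MAX_F1: maximal F1; ties broken toward higher precision, then lower
    threshold.  PRECISION_FLOOR: the highest-recall point with precision >=
    the floor (raises naming the best attainable precision if none).
    """
    if not points:
        raise ValueError("empty precision-recall point list")
    eps = 1e-12
    if rule is ThresholdRule.MAX_F1:
        best = None
        for pt in points:
            f1 = _f1(pt.precision, pt.recall)
            if best is None:
                best, best_f1 = pt, f1
                continue
            if f1 > best_f1 + eps:
                best, best_f1 = pt, f1
            elif abs(f1 - best_f1) <= eps:
                if pt.precision > best.precision + eps or (
                    abs(pt.precision - best.precision) <= eps and pt.threshold < best.threshold
                ):
                    best, best_f1 = pt, f1
        return Threshold(best.threshold, rule, best.precision, best.recall)
    if rule is ThresholdRule.PRECISION_FLOOR:
        if precision_floor is None:
            raise ValueError("PRECISION_FLOOR requires a precision_floor value")
        eligible = [pt for pt in points if pt.precision >= precision_floor]
        if not eligible:
            best_attainable = max(pt.precision for pt in points)
            raise ValueError(
                f"precision floor {precision_floor:.3f} unattainable; "
                f"best attainable precision is {best_attainable:.3f}"
            )
        best = eligible[0]
        for pt in eligible[1:]:
            if pt.recall > best.recall + eps or (
                abs(pt.recall - best.recall) <= eps and pt.precision > best.precision + eps
            ):
                best = pt
        return Threshold(best.threshold, rule, best.precision, best.recall)
    raise ValueError(f"unknown threshold rule {rule!r}")
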