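"""Association counting, scoring, claim aggregation, and threshold selection."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lateraleye.aop_model import (
    AssociationTable,
    PRPoint,
    ScoreMode,
    Threshold,
    ThresholdRule,
    _LevelCounts,
    association_score,
    precision_recall_points,
    score_claim,
    select_threshold,
    train_associations,
)
from lateraleye.claims_model import ClaimSet, CodeMap, System
from lateraleye.synthetic_data import GeneratorConfig, build_code_universe, simulate_claims

from conftest import make_claim, make_set


def _toy_corpus(universe):
    """3 claims pairing proc(0,R) with its exact diagnosis, 1 claim for part 1."""
    p0, d0 = universe.proc_code(0, 0), universe.diag_lateral(0, 0)
    p1, d1 = universe.proc_code(1, 0), universe.diag_lateral(1, 0)
    claims = [make_claim([p0], [d0], claim_id=f"A{i}") for i in range(3)]
    claims.append(make_claim([p1], [d1], claim_id="B0"))
    return ClaimSet(claims), (p0, d0), (p1, d1)


def test_pair_counting_and_smoothed_confidence(small_universe):
    corpus, (p0, d0), _ = _toy_corpus(small_universe)
    table = train_associations(corpus, small_universe.code_map, alpha=1.0)
    lvl = table.levels["code"]
    assert lvl.pair_counts[(p0, d0)] == 3
    assert lvl.proc_marginals[p0] == 3 and lvl.diag_marginals[d0] == 3
    assert table.n_claims_trained == 4
    # universe of 2 distinct procedure keys: s = (3 + 1) / (3 + 1 * 2) = 0.8
    assert association_score(table, small_universe.code_map, p0, d0) == pytest.approx(0.8)


def test_duplicate_codes_counted_once_per_claim(small_universe):
    p0, d0 = small_universe.proc_code(0, 0), small_universe.diag_lateral(0, 0)
    corpus = make_set(make_claim([p0, p0], [d0, d0]))
    table = train_associations(corpus, small_universe.code_map)
    assert table.levels["code"].pair_counts[(p0, d0)] == 1
    assert table.levels["code"].diag_marginals[d0] == 1


def test_empty_corpus_rejected(small_universe):
    with pytest.raises(ValueError, match="empty"):
        train_associations(ClaimSet([]), small_universe.code_map)


def test_confidence_normalizes_over_procedure_universe(small_universe):
    corpus, _, _ = _toy_corpus(small_universe)
    table = train_associations(corpus, small_universe.code_map, alpha=1.0)
    for name, lvl in table.levels.items():
        for dk in lvl.diag_marginals:
            total = sum(
                (lvl.pair_counts.get((pk, dk), 0) + 1.0)
                / (lvl.diag_pair_mass[dk] + 1.0 * lvl.n_procedure_keys)
                for pk in lvl.proc_marginals
            )
            assert total == pytest.approx(1.0)


def test_never_cooccurring_pair_scores_near_floor(small_universe):
    corpus, (p0, _), (_, d1) = _toy_corpus(small_universe)
    table = train_associations(corpus, small_universe.code_map, alpha=1.0)
    floor = 1.0 / 2  # alpha/(alpha*|P|) upper bound scale with |P|=2
    s = association_score(table, small_universe.code_map, p0, d1)
    assert s == pytest.approx((0 + 1.0) / (1 + 1.0 * 2))
    assert s < 0.8


def test_lift_independence_maps_to_half(small_universe):
    # c(p,d) = c(p)c(d)/n exactly: 4 claims, p and d each in 2, together in 1
    p0, d0 = small_universe.proc_code(0, 0), small_universe.diag_lateral(0, 0)
    p1, d1 = small_universe.proc_code(1, 0), small_universe.diag_lateral(1, 0)
    corpus = make_set(
        make_claim([p0], [d0], claim_id="1"),
        make_claim([p0], [d1], claim_id="2"),
        make_claim([p1], [d0], claim_id="3"),
        make_claim([p1], [d1], claim_id="4"),
    )
    table = train_associations(corpus, small_universe.code_map, alpha=1e-9, mode=ScoreMode.LIFT)
    assert association_score(table, small_universe.code_map, p0, d0) == pytest.approx(0.5, abs=1e-6)


def test_score_monotone_in_pair_count():
    """Brute force over count grids: raising c(p,d) with marginals fixed never
    lowers the score, in either mode."""
    for mode in ScoreMode:
        for c_p in range(1, 21, 4):
            for c_d in range(1, 21, 4):
                last = -1.0
                for c_pd in range(0, min(c_p, c_d) + 1):
                    lvl = _LevelCounts()
                    lvl.pair_counts[("P", "D")] = c_pd
                    lvl.proc_marginals["P"] = c_p
                    lvl.proc_marginals["P2"] = 5
                    lvl.diag_marginals["D"] = c_d
                    lvl.diag_pair_mass["D"] = c_d  # one procedure per claim
                    table = AssociationTable(
                        levels={"code": lvl}, n_claims_trained=40,
                        smoothing_alpha=1.0, score_mode=mode, backoff_levels=("code",),
                    )
                    from lateraleye.aop_model import _score_at_level

                    s = _score_at_level(table, lvl, "P", "D")
                    assert 0.0 <= s <= 1.0
                    assert s >= last
                    last = s


def test_unseen_diagnosis_falls_through_backoff(small_universe):
    """A novel full code sharing a trained body part scores at the stripped
    level; a completely unknown code scores at the smoothing floor."""
    corpus, (p0, d0), _ = _toy_corpus(small_universe)
    table = train_associations(corpus, small_universe.code_map)
    cmap = small_universe.code_map.with_entries(
        {
            (System.CM, "M00X"): dataclasses.replace(
                cmap_meta := small_universe.code_map.resolve(d0, System.CM), code="M00X"
            )
        }
    )
    novel = association_score(table, cmap, p0, "M00X")  # same part+side, unseen code
    unknown = association_score(table, cmap, p0, "Q999")
    assert novel > unknown


def test_claim_score_min_over_procedures_max_over_diagnoses(small_universe):
    corpus, (p0, d0), (p1, d1) = _toy_corpus(small_universe)
    table = train_associations(corpus, small_universe.code_map)
    threshold = Threshold(0.5, ThresholdRule.MAX_F1, 1.0, 1.0)
    justified = score_claim(make_claim([p0], [d0, d1]), table, small_universe.code_map, threshold)
    assert justified.claim_score == max(
        association_score(table, small_universe.code_map, p0, d)
        for d in (d0, d1)
    )
    assert not justified.flagged

    mixed = score_claim(make_claim([p0, p1], [d0]), table, small_universe.code_map, threshold)
    assert mixed.claim_score == min(s for _, s, _ in mixed.per_procedure_scores)
    assert mixed.claim_score < justified.claim_score  # p1 unsubstantiated by d0


def test_table_json_round_trip(tmp_path, small_universe):
    corpus, (p0, d0), (_, d1) = _toy_corpus(small_universe)
    table = train_associations(corpus, small_universe.code_map)
    back = AssociationTable.from_json(table.to_json(tmp_path / "model.json"))
    for d in (d0, d1):
        assert association_score(back, small_universe.code_map, p0, d) == pytest.approx(
            association_score(table, small_universe.code_map, p0, d)
        )


# -- precision-recall -------------------------------------------------------

def _pr_oracle(scores, labels, thresholds):
    """Quadratic-time recomputation of precision/recall at given thresholds."""
    out = {}
    n_pos = sum(labels)
    for t in thresholds:
        flagged = [(s, y) for s, y in zip(scores, labels) if s < t]
        if not flagged:
            continue
        tp = sum(y for _, y in flagged)
        out[t] = (tp / len(flagged), tp / n_pos)
    return out


def test_perfectly_separated_scores_reach_precision_and_recall_one():
    scores = [0.1, 0.2, 0.8, 0.9]
    labels = [True, True, False, False]
    points = precision_recall_points(scores, labels)
    assert any(p.precision == 1.0 and p.recall == 1.0 for p in points)
    # the flag-everything end of the sweep: recall 1, precision = prevalence
    last = points[-1]
    assert last.recall == 1.0 and last.precision == pytest.approx(0.5)


def test_recall_nondecreasing_and_oracle_agreement():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = int(rng.integers(5, 40))
        scores = rng.random(n).round(2)  # ties on purpose
        labels = rng.random(n) < 0.4
        if not labels.any():
            labels[int(rng.integers(0, n))] = True
        points = precision_recall_points(scores, labels.tolist())
        oracle = _pr_oracle(scores.tolist(), labels.tolist(), [p.threshold for p in points])
        for prev, cur in zip(points, points[1:]):
            assert cur.recall >= prev.recall
        for p in points:
            op, orr = oracle[p.threshold]
            assert p.precision == pytest.approx(op)
            assert p.recall == pytest.approx(orr)


def test_pr_points_are_sklearn_operating_points():
    """Every (precision, recall) point of the strict-below sweep appears on
    scikit-learn's curve for the negated scores (flag s < t is flag -s >= -t
    at the preceding distinct value)."""
    from sklearn.metrics import precision_recall_curve

    rng = np.random.default_rng(5)
    for _ in range(50):
        n = int(rng.integers(5, 50))
        scores = rng.random(n).round(2)
        labels = rng.random(n) < 0.4
        if not labels.any():
            labels[0] = True
        ours = {
            (round(p.precision, 9), round(p.recall, 9))
            for p in precision_recall_points(scores.tolist(), labels.tolist())
        }
        prec, rec, _ = precision_recall_curve(labels, -scores)
        theirs = {(round(p, 9), round(r, 9)) for p, r in zip(prec[:-1], rec[:-1])}
        assert ours <= theirs


def test_zero_positives_rejected():
    with pytest.raises(ValueError, match="positive"):
        precision_recall_points([0.1, 0.2], [False, False])


# -- threshold selection ----------------------------------------------------

def test_single_point_is_selected():
    pt = PRPoint(0.3, 0.9, 0.4, 10, 9)
    th = select_threshold([pt])
    assert (th.value, th.precision, th.recall) == (0.3, 0.9, 0.4)


def test_f1_tie_breaks_toward_higher_precision():
    # F1(0.9, 0.5) == F1(0.5, 0.9) == 0.642857...: the tie goes to precision
    a = PRPoint(0.2, 0.9, 0.5, 10, 9)
    b = PRPoint(0.4, 0.5, 0.9, 20, 10)
    th = select_threshold([a, b], ThresholdRule.MAX_F1)
    assert th.precision == 0.9 and th.value == 0.2


def test_precision_floor_picks_highest_recall_by_enumeration():
    rng = np.random.default_rng(7)
    points = [
        PRPoint(float(t), float(p), float(r), 10, 5)
        for t, p, r in zip(rng.random(50), rng.random(50), rng.random(50))
    ]
    floor = 0.6
    th = select_threshold(points, ThresholdRule.PRECISION_FLOOR, precision_floor=floor)
    eligible = [p for p in points if p.precision >= floor]
    assert th.precision >= floor
    assert th.recall == max(p.recall for p in eligible)


def test_unattainable_floor_names_best_precision():
    points = [PRPoint(0.2, 0.7, 0.5, 10, 7)]
    with pytest.raises(ValueError, match="0.700"):
        select_threshold(points, ThresholdRule.PRECISION_FLOOR, precision_floor=0.95)
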