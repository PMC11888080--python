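"""Claim-table I/O, validation totality, and code-map resolution."""

import pytest
from hypothesis import given, settings, strategies as st

from lateraleye.claims_model import (
    ClaimSet,
    ClaimValidationError,
    CodeMap,
    CodeMapError,
    CodeMeta,
    CodedClaim,
    Laterality,
    SchemaError,
    System,
    read_claims,
    write_claims,
)
from lateraleye.synthetic_data import ErrorKind, GroundTruth, NonErrorKind

from conftest import make_claim


# -- I/O round trips --------------------------------------------------------

pcs_codes = st.text(alphabet="0123456789ABCDEFGHJKLMNPQRSTVWXYZ", min_size=7, max_size=7)
cm_codes = st.builds(
    lambda head, tail: head + tail,
    st.sampled_from("ABCDEFGHIJKLMNZ"),
    st.text(alphabet="0123456789ABCDX", min_size=2, max_size=6),
)
truths = st.one_of(
    st.none(),
    st.builds(
        lambda err: GroundTruth(
            is_error=err,
            error_kind=ErrorKind.SAME_BODY_PART if err else ErrorKind.NONE,
            nonerror_kind=NonErrorKind.NONE if err else NonErrorKind.GENERAL_DIAGNOSIS,
            justifying_diagnosis_index=0,
        ),
        st.booleans(),
    ),
)


@st.composite
def claim_sets(draw):
    n = draw(st.integers(min_value=0, max_value=6))
    claims = [
        CodedClaim(
            claim_id=f"C{i}",
            year=draw(st.integers(min_value=2017, max_value=2021)),
            specialty_code=draw(st.sampled_from(["20", "99"])),
            procedure_codes=tuple(draw(st.lists(pcs_codes, min_size=1, max_size=3))),
            diagnosis_codes=tuple(draw(st.lists(cm_codes, min_size=1, max_size=4))),
            truth=draw(truths),
        )
        for i in range(n)
    ]
    return ClaimSet(claims, provenance="hypothesis")


@pytest.mark.parametrize("fmt", ["csv", "parquet"])
@settings(max_examples=30, deadline=None, derandomize=True)
@given(claims=claim_sets())
def test_round_trip_preserves_all_fields(claims, fmt, tmp_path_factory):
    tmp = tmp_path_factory.mktemp("io")
    path = write_claims(claims, tmp / f"claims.{fmt}", fmt)
    back = read_claims(path, fmt)
    assert len(back) == len(claims)
    for a, b in zip(claims, back):
        assert (a.claim_id, a.year, a.specialty_code) == (b.claim_id, b.year, b.specialty_code)
        assert a.procedure_codes == b.procedure_codes
        assert a.diagnosis_codes == b.diagnosis_codes
        assert a.truth == b.truth


def test_well_formed_csv_reads_back(tmp_path):
    path = tmp_path / "claims.csv"
    claims = ClaimSet(
        [make_claim(["0SRC0J9"], ["M1712", "I10"], claim_id=f"C{i}") for i in range(3)]
    )
    write_claims(claims, path)
    assert len(read_claims(path)) == 3


def test_empty_set_writes_header_only(tmp_path):
    path = write_claims(ClaimSet([]), tmp_path / "empty.csv")
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("claim_id,")
    assert len(read_claims(path)) == 0


def test_short_pcs_code_is_a_row_level_error(tmp_path):
    path = tmp_path / "claims.csv"
    path.write_text(
        "claim_id,year,specialty_code,procedure_codes,diagnosis_codes\n"
        "C1,2020,20,0SRC0J,M1712\n"
        "C2,2020,20,0SRC0J9,M1712\n"
    )
    with pytest.raises(ClaimValidationError) as err:
        read_claims(path)
    assert any("0SRC0J" in str(e) for e in err.value.row_errors)
    accepted, rejected = read_claims(path, errors="collect")
    assert len(accepted) + len({e.row_index for e in rejected}) == 2


def test_missing_column_names_the_column(tmp_path):
    path = tmp_path / "claims.csv"
    path.write_text("claim_id,year,procedure_codes,diagnosis_codes\nC1,2020,0SRC0J9,M1712\n")
    with pytest.raises(SchemaError, match="specialty_code"):
        read_claims(path)


def test_duplicate_claim_id_is_reported(tmp_path):
    path = tmp_path / "claims.csv"
    path.write_text(
        "claim_id,year,specialty_code,procedure_codes,diagnosis_codes\n"
        "C1,2020,20,0SRC0J9,M1712\nC1,2020,20,0SRB049,M1611\n"
    )
    with pytest.raises(ClaimValidationError, match="duplicate claim_id"):
        read_claims(path)


def test_empty_code_list_is_a_row_error(tmp_path):
    path = tmp_path / "claims.csv"
    path.write_text(
        "claim_id,year,specialty_code,procedure_codes,diagnosis_codes\nC1,2020,20,,M1712\n"
    )
    with pytest.raises(ClaimValidationError, match="no procedure codes"):
        read_claims(path)


# -- code map ---------------------------------------------------------------

@pytest.mark.parametrize(
    "code,system,body_part,laterality",
    [
        ("0SRC0J9", System.PCS, "knee_joint", Laterality.RIGHT),
        ("0SRB049", System.PCS, "hip_joint", Laterality.LEFT),
        ("0Y6H0Z2", System.PCS, "lower_leg", Laterality.RIGHT),
        ("M1712", System.CM, "knee", Laterality.LEFT),
        ("M75120", System.CM, "shoulder", Laterality.UNSPECIFIED_SIDE),
        ("M1611", System.CM, "hip", Laterality.RIGHT),
    ],
)
def test_default_map_resolves_known_families(default_map, code, system, body_part, laterality):
    meta = default_map.resolve(code, system)
    assert (meta.body_part, meta.laterality) == (body_part, laterality)


def test_proximity_is_symmetric_across_aliases(default_map):
    assert default_map.proximate("shoulder_joint", "humerus")
    assert default_map.proximate("humerus", "shoulder_joint")
    assert not default_map.proximate("knee_joint", "humerus")
    assert not default_map.proximate("knee_joint", "knee")  # same site, not "proximate"


def test_unknown_code_falls_back_to_general(default_map):
    meta = default_map.resolve("Q9999", System.CM)
    assert meta.body_part is None and meta.is_general
    proc = default_map.resolve("XXXXXXX", System.PCS)
    assert proc.body_part is None and not proc.is_general


def test_prefix_resolution_stable_under_nonconflicting_additions(default_map):
    before = default_map.resolve("M1712", System.CM)
    extended = default_map.with_entries(
        {(System.CM, "M99"): CodeMeta(code="M99", system=System.CM, body_part="spine",
                                      laterality=Laterality.NO_LATERALITY)}
    )
    assert extended.resolve("M1712", System.CM) == before
    assert extended.resolve("M9901", System.CM).body_part == "spine"


def test_longest_prefix_wins():
    cmap = CodeMap(
        {
            (System.CM, "M17"): CodeMeta("M17", System.CM, "knee", Laterality.NO_LATERALITY),
            (System.CM, "M171"): CodeMeta("M171", System.CM, "knee", Laterality.RIGHT),
        }
    )
    assert cmap.resolve("M1712", System.CM).laterality is Laterality.RIGHT
    assert cmap.resolve("M1702", System.CM).laterality is Laterality.NO_LATERALITY


def test_conflicting_duplicate_prefix_rejected():
    rows = [
        {"code_or_prefix": "M17", "system": "CM", "body_part": "knee", "laterality": "RIGHT"},
        {"code_or_prefix": "M17", "system": "CM", "body_part": "knee", "laterality": "LEFT"},
    ]
    with pytest.raises(CodeMapError, match="conflicting duplicate prefix"):
        CodeMap.from_rows(rows)


def test_reflexive_proximity_rejected():
    with pytest.raises(CodeMapError, match="irreflexive"):
        CodeMap({}, proximity=[("knee", "knee")])


def test_code_meta_invariants():
    with pytest.raises(CodeMapError):
        CodeMeta("X", System.CM, body_part=None, laterality=Laterality.LEFT)
    with pytest.raises(CodeMapError):
        CodeMeta("X", System.CM, body_part="knee", laterality=Laterality.LEFT, is_general=True)
    with pytest.raises(CodeMapError):
        CodeMeta("X", System.CM, is_infusion_device_insertion=True)
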