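import pytest

from lateraleye.claims_model import ClaimSet, CodedClaim, load_default_code_map
from lateraleye.synthetic_data import GeneratorConfig, build_code_universe, simulate_claims


@pytest.fixture(scope="session")
def default_map():
    return load_default_code_map()


@pytest.fixture(scope="session")
def small_universe():
    """A compact synthetic code universe shared across tests."""
    return build_code_universe(GeneratorConfig(n_claims=1, n_body_parts=8, seed=0))


@pytest.fixture(scope="session")
def noiseless_config():
    """Exactly documented conditions: every review label is determined."""
    return GeneratorConfig(
        n_claims=5_000,
        n_body_parts=8,
        p_unspecified_side=0.0,
        p_no_laterality=0.0,
        p_general_justification=0.0,
        p_proximity_pair=0.0,
        p_lateralized_comorbidity=0.0,
        p_infusion_only=0.0,
        p_other_specialty=0.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def noiseless_corpus(noiseless_config):
    universe = build_code_universe(noiseless_config)
    return universe, simulate_claims(noiseless_config, universe)


def make_claim(procs, diags, claim_id="C1", year=2020, specialty="20", truth=None):
    return CodedClaim(
        claim_id=claim_id,
        year=year,
        specialty_code=specialty,
        procedure_codes=tuple(procs),
        diagnosis_codes=tuple(diags),
        truth=truth,
    )


def make_set(*claims):
    return ClaimSet(list(claims))
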