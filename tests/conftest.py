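import pytest

from ehrcohort import (OracleBackend, af_progression, default_params,
                       generate_cohort, hf_decompensation)


@pytest.fixture(scope="session")
def af_spec():
    return af_progression()


@pytest.fixture(scope="session")
def hf_spec():
    return hf_decompensation()


@pytest.fixture(scope="session")
def af_cohort(af_spec):
    """Small clean AF cohort (no distractors, no contrary ECGs)."""
    params = default_params(af_spec, seed=11, n_patients=60, negation_rate=0.2)
    return generate_cohort(params, af_spec)


@pytest.fixture(scope="session")
def af_oracle(af_cohort, af_spec):
    return OracleBackend(af_cohort, af_spec)
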