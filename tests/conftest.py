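import pytest

from pitnet_triage import build_reference_cohort, load_table3_profiles


@pytest.fixture(scope="session")
def reference_cohort():
    return build_reference_cohort()


@pytest.fixture(scope="session")
def table3_records():
    return load_table3_profiles()
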