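import pytest

from ozonemeta import presets


@pytest.fixture(scope="session")
def study_records():
    """The seven shipped study records (three IM RCTs, one ID RCT, three ID cohorts)."""
    return presets.study_table()


@pytest.fixture(scope="session")
def intramuscular_rcts(study_records):
    return [s for s in study_records if s.route.value == "intramuscular"]
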