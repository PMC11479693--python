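import pytest

from ffworkup import datasets


@pytest.fixture(scope="session")
def study_tables():
    """Checksum-verified packaged study tables."""
    return datasets.fixtures()


@pytest.fixture(scope="session")
def variant_records(study_tables):
    return study_tables["variant_records"]


@pytest.fixture(scope="session")
def rosters(study_tables):
    return study_tables["rosters"]


@pytest.fixture(scope="session")
def cycles(study_tables):
    return study_tables["cycles"]


@pytest.fixture(scope="session")
def moat_table(study_tables):
    return study_tables["moat"]
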