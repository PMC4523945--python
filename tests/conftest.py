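import pytest

from snpmeta import load_fixture


@pytest.fixture(scope="session")
def rs3803662():
    return load_fixture("rs3803662")


@pytest.fixture(scope="session")
def rs12443621():
    return load_fixture("rs12443621")


@pytest.fixture(scope="session")
def rs8051542():
    return load_fixture("rs8051542")


@pytest.fixture(scope="session")
def he_2014_rs3803662(rs3803662):
    """The He 2014 study: cases 271/280/72, controls 270/278/72."""
    return next(s for s in rs3803662.studies if s.study_id == "He 2014")
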