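import pytest

from phenocheck import generate_clean
from phenocheck.checks import CheckConfig
from phenocheck.fixtures import FixtureSpec


@pytest.fixture(scope="session")
def clean_pair():
    """The default clean fixture: 100 subjects x 12 variables, seed 42."""
    return generate_clean(FixtureSpec())


@pytest.fixture()
def strict_config():
    """Panel config with mixed-missingness encoding escalated to a failure."""
    return CheckConfig(na_severity="fail")
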