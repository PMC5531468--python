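import pytest

from cardiotriage import MAFThresholdPolicy, load_default_map
from cardiotriage.synthetic_cohort import make_paper_fixtures


@pytest.fixture(scope="session")
def paper():
    """The published worked example: 28 variants, 29 observations, 38 patients."""
    return make_paper_fixtures()


@pytest.fixture(scope="session")
def ttn_map():
    return load_default_map()


@pytest.fixture()
def default_policy():
    return MAFThresholdPolicy()
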