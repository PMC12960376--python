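import pytest
from hypothesis import HealthCheck, settings

from ea2struct import (
    SyntheticGeneSpec,
    load_ea2_cohort,
    make_synthetic_gene,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_gene():
    """Default 5-exon toy transcript and its expected-consequence catalog."""
    return make_synthetic_gene(SyntheticGeneSpec())


@pytest.fixture(scope="session")
def cohort():
    """Packaged 13-patient cohort table."""
    return load_ea2_cohort()
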