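import pytest
from hypothesis import HealthCheck, settings

import afterfit as af

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def as_case():
    """Default AS-like synthetic fixture at the published operating point."""
    return af.default_as_case()


@pytest.fixture(scope="session")
def periodic_case():
    """Same fixture but with the periodic initial pressure (self-consistent)."""
    return af.make_case(af.SynthSpec(), periodic=True)


@pytest.fixture(scope="session")
def as_results(as_case):
    """A reference fit of the default fixture, shared across tests."""
    model = af.Wk3Model(as_case.q, as_case.measured)
    return model.fit(seed=1)
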