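from datetime import date

import pytest
from hypothesis import HealthCheck, settings

from addrexp import StudyMember

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    # the fixtures drawn into property tests are frozen dataclasses, safe to reuse
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def member_term() -> StudyMember:
    """Full-term member: DoB 1991-06-15, 40 completed weeks (DoC 1990-09-07)."""
    return StudyMember("m-term", date(1991, 6, 15), 40)


@pytest.fixture
def member_preterm() -> StudyMember:
    """Premature member (26 weeks): no third trimester."""
    return StudyMember("m-preterm", date(1991, 6, 15), 26)
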