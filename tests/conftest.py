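import pytest

from rpmplan import ProviderPool, Scenario


@pytest.fixture
def baseline_pool() -> ProviderPool:
    """The study clinic's workforce: 3 reviewers, 4 h/week, 10 min/review."""
    return ProviderPool(n_providers=3, hours_per_period=4, minutes_per_review=10)


@pytest.fixture
def baseline_scenario(baseline_pool) -> Scenario:
    """Baseline scenario anchored to the clinic's reported 73% coverage.

    The clinic never published its absolute demand; it is back-solved from
    the reported coverage and the 72 reviews/week capacity (~98.63
    contacts/week).
    """
    return Scenario.from_reported_coverage(baseline_pool, 73.0)
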