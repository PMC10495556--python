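"""Unit and property tests for the deterministic demand-capacity model."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpmplan import (
    Cohort,
    InvalidParameterError,
    ProviderPool,
    Scenario,
    coverage,
    project_population,
    projected_capacity,
    projected_demand,
    scale_coverage,
)

cohort_st = st.builds(
    Cohort,
    name=st.just("c"),
    enrolled=st.floats(0, 500),
    contact_fraction=st.floats(0, 1),
    review_frequency=st.floats(0.01, 2),
    new_per_period=st.floats(0, 20),
    graduation_fraction=st.floats(0, 1),
)

pool_st = st.builds(
    ProviderPool,
    n_providers=st.integers(1, 20),
    hours_per_period=st.floats(0.5, 40),
    minutes_per_review=st.floats(1, 60),
)


class TestProjectedDemand:
    @pytest.mark.parametrize(
        "cohorts, expected",
        [
            ([Cohort("a", enrolled=0, contact_fraction=0.7, new_per_period=0)], 0.0),
            (
                [Cohort("a", enrolled=38, contact_fraction=0.25, new_per_period=2)],
                10.0,
            ),
            (
                [
                    Cohort("w", enrolled=10, contact_fraction=0.5),
                    Cohort("m", enrolled=40, contact_fraction=0.5,
                           review_frequency=0.25),
                ],
                10.0,
            ),
        ],
        ids=["empty-population", "single-cohort", "additive-over-cadences"],
    )
    def test_examples(self, cohorts, expected):
        assert projected_demand(cohorts) == pytest.approx(expected)

    @given(cohorts=st.lists(cohort_st, min_size=1, max_size=4))
    @settings(derandomize=True, max_examples=100)
    def test_additive_and_homogeneous(self, cohorts):
        """D is additive over cohorts and degree-1 homogeneous in (N+A)."""
        total = projected_demand(cohorts)
        assert total == pytest.approx(sum(projected_demand([c]) for c in cohorts))
        doubled = [
            Cohort(c.name, 2 * c.enrolled, c.contact_fraction, c.review_frequency,
                   2 * c.new_per_period, c.graduation_fraction)
            for c in cohorts
        ]
        assert projected_demand(doubled) == pytest.approx(2 * total)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"enrolled": -1, "contact_fraction": 0.5},
            {"enrolled": 10, "contact_fraction": 1.5},
            {"enrolled": 10, "contact_fraction": 0.5, "review_frequency": 0},
            {"enrolled": 10, "contact_fraction": 0.5, "graduation_fraction": 1.1},
            {"enrolled": 10, "contact_fraction": 0.5, "new_per_period": -2},
        ],
    )
    def test_invalid_cohort_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            Cohort(name="bad", **kwargs)


class TestProjectedCapacity:
    @pytest.mark.parametrize(
        "m, h, t, expected",
        [(3, 4, 10, 72.0), (1, 1, 60, 1.0), (5, 4, 10, 120.0)],
    )
    def test_examples(self, m, h, t, expected):
        assert projected_capacity(ProviderPool(m, h, t)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_providers": 0, "hours_per_period": 4, "minutes_per_review": 10},
            {"n_providers": 3, "hours_per_period": 0, "minutes_per_review": 10},
            {"n_providers": 3, "hours_per_period": 4, "minutes_per_review": -1},
        ],
    )
    def test_invalid_pool_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ProviderPool(**kwargs)

    @given(pool=pool_st, factor=st.integers(2, 5))
    @settings(derandomize=True, max_examples=50)
    def test_provider_hour_trade_invariance(self, pool, factor):
        """(m, h) and (m*c, h/c) deliver identical capacity."""
        traded = ProviderPool(
            pool.n_providers * factor,
            pool.hours_per_period / factor,
            pool.minutes_per_review,
        )
        assert projected_capacity(traded) == pytest.approx(projected_capacity(pool))

    def test_override_replaces_derived_rate(self):
        pool = ProviderPool(2, 5, 10, review_capacity_override=4.0)
        assert pool.reviews_per_provider_hour == 4.0
        assert projected_capacity(pool) == pytest.approx(40.0)


class TestCoverage:
    def test_baseline_back_solved(self):
        # demand implied by 73% reported coverage at 72 reviews/week
        assert coverage(100 * 72 / 73, 72).reported_coverage == 73

    def test_faster_reviews_reach_91(self):
        assert coverage(100 * 72 / 73, 90).reported_coverage == 91

    def test_zero_demand_fully_covered(self):
        result = coverage(0, 0)
        assert result.coverage == 100.0
        assert result.reported_coverage == 100
        assert math.isinf(result.raw_coverage)

    def test_reported_rounds_half_up(self):
        assert coverage(100.0, 91.25).reported_coverage == 91
        assert coverage(100.0, 91.5).reported_coverage == 92

    @given(
        demand=st.floats(0.1, 500),
        capacity=st.floats(0, 500),
        extra=st.floats(0.1, 100),
    )
    @settings(derandomize=True, max_examples=100)
    def test_monotone_and_capped(self, demand, capacity, extra):
        base = coverage(demand, capacity)
        assert base.coverage <= 100.0
        assert base.coverage <= base.raw_coverage
        assert coverage(demand, capacity + extra).coverage >= base.coverage
        assert coverage(demand + extra, capacity).coverage <= base.coverage

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            coverage(-1, 10)
        with pytest.raises(InvalidParameterError):
            coverage(10, -1)


class TestScaleCoverage:
    def test_review_time_scenario(self, baseline_pool):
        faster = ProviderPool(3, 4, 8)
        assert round(scale_coverage(73, baseline_pool, faster)) == 91

    def test_hiring_scenario_caps(self, baseline_pool):
        bigger = ProviderPool(5, 4, 10)
        assert scale_coverage(73, baseline_pool, bigger) == 100.0

    def test_identity(self, baseline_pool):
        assert scale_coverage(73, baseline_pool, baseline_pool) == pytest.approx(73.0)

    def test_invalid_base_rejected(self, baseline_pool):
        with pytest.raises(InvalidParameterError):
            scale_coverage(0, baseline_pool, baseline_pool)

    @given(pool=pool_st, new_pool=pool_st, demand=st.floats(1, 500))
    @settings(derandomize=True, max_examples=100)
    def test_agrees_with_coverage_oracle(self, pool, new_pool, demand):
        """Scaling a base percentage equals recomputing coverage at fixed demand."""
        base = coverage(demand, projected_capacity(pool)).coverage
        if base <= 0 or base >= 100:  # anchor must be an interior percentage
            return
        scaled = scale_coverage(base, pool, new_pool)
        direct = coverage(demand, projected_capacity(new_pool)).coverage
        assert scaled == pytest.approx(direct, abs=1e-9)


class TestProjectPopulation:
    def test_steady_state(self):
        c = Cohort("a", enrolled=100, contact_fraction=0.5)
        traj = project_population([c], horizon=5)
        assert traj.counts["a"].tolist() == [100.0] * 5

    def test_hand_recurrence(self):
        c = Cohort("a", enrolled=0, contact_fraction=0.5,
                   new_per_period=10, graduation_fraction=0.5)
        traj = project_population([c], horizon=3)
        assert traj.counts["a"].tolist() == [0.0, 10.0, 15.0]

    def test_converges_to_fixed_point(self):
        c = Cohort("a", enrolled=30, contact_fraction=0.5,
                   new_per_period=10, graduation_fraction=0.1)
        traj = project_population([c], horizon=200)
        assert traj.counts["a"].iloc[-1] == pytest.approx(100.0, abs=1e-6)

    @given(
        enrolled=st.floats(0, 200),
        new=st.floats(0, 10),
        horizon=st.integers(1, 30),
    )
    @settings(derandomize=True, max_examples=50)
    def test_no_graduation_growth_is_linear(self, enrolled, new, horizon):
        c = Cohort("a", enrolled=enrolled, contact_fraction=0.5, new_per_period=new)
        traj = project_population([c], horizon=horizon)
        for k in range(horizon):
            assert traj.counts["a"].iloc[k] == pytest.approx(enrolled + k * new)

    def test_bad_horizon_rejected(self):
        with pytest.raises(InvalidParameterError):
            project_population([], horizon=0)


class TestScenario:
    def test_anchoring_reproduces_reported_coverage(self, baseline_pool):
        for pct in (20, 50, 73, 99):
            s = Scenario.from_reported_coverage(baseline_pool, pct)
            assert s.coverage().reported_coverage == pct
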