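"""Deterministic demand-capacity model for remote patient monitoring (RPM).

The model treats one *review period* (one week by default) as its time unit.
A clinic serves one or more patient cohorts; each cohort has a review cadence
``f`` (reviews per patient per period; 1.0 = every period, 0.25 = every 4th
period) and a contact fraction ``p`` (fraction of reviewed patients whose data
triggers outreach).  Expected demand, in review-plus-contact events per
period, is

    D = sum_i f_i * p_i * (N_i + A_i)

where ``N_i`` is the enrolled count and ``A_i`` the expected newly enrolled
patients per period.  A pool of ``m`` reviewers, each giving ``h`` hours per
period at ``t`` minutes per patient review, delivers

    K = (60 / t) * m * h

reviews per period.  Coverage is capacity as a percent of demand, capped at
100% for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "Cohort",
    "ProviderPool",
    "CoverageResult",
    "PopulationTrajectory",
    "Scenario",
    "projected_demand",
    "projected_capacity",
    "coverage",
    "scale_coverage",
    "project_population",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (for x >= 0)."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Cohort:
    """A patient sub-population sharing one review cadence and contact fraction.

    Parameters
    ----------
    name
        Label for reporting.
    enrolled
        Current enrolled patient count ``N`` (>= 0).
    contact_fraction
        Fraction ``p`` in [0, 1] of reviewed patients requiring contact.
    review_frequency
        Reviews per patient per period ``f`` (> 0); 0.25 encodes a monthly
        cadence inside a weekly period (4 weeks/month).
    new_per_period
        Expected newly enrolled patients per period ``A`` (>= 0, fractional ok).
    graduation_fraction
        Fraction ``g`` in [0, 1] of enrolled patients leaving per period.
    """

    name: str
    enrolled: float
    contact_fraction: float
    review_frequency: float = 1.0
    new_per_period: float = 0.0
    graduation_fraction: float = 0.0

    def __post_init__(self):
        if self.enrolled < 0:
            raise InvalidParameterError(f"cohort {self.name!r}: enrolled must be >= 0")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise InvalidParameterError(
                f"cohort {self.name!r}: contact_fraction must be in [0, 1]"
            )
        if self.review_frequency <= 0:
            raise InvalidParameterError(
                f"cohort {self.name!r}: review_frequency must be > 0"
            )
        if self.new_per_period < 0:
            raise InvalidParameterError(
                f"cohort {self.name!r}: new_per_period must be >= 0"
            )
        if not 0.0 <= self.graduation_fraction <= 1.0:
            raise InvalidParameterError(
                f"cohort {self.name!r}: graduation_fraction must be in [0, 1]"
            )


@dataclass(frozen=True)
class ProviderPool:
    """The reviewer workforce.

    ``review_capacity_override``, when set, is a direct patients-per-
    provider-hour figure that replaces the derived rate 60/minutes_per_review.
    """

    n_providers: int
    hours_per_period: float
    minutes_per_review: float
    review_capacity_override: float | None = None

    def __post_init__(self):
        if self.n_providers < 1 or int(self.n_providers) != self.n_providers:
            raise InvalidParameterError("n_providers must be a positive integer")
        if self.hours_per_period <= 0:
            raise InvalidParameterError("hours_per_period must be > 0")
        if self.minutes_per_review <= 0:
            raise InvalidParameterError("minutes_per_review must be > 0")
        if self.review_capacity_override is not None and self.review_capacity_override <= 0:
            raise InvalidParameterError("review_capacity_override must be > 0")

    @property
    def reviews_per_provider_hour(self) -> float:
        """Patients one provider can process per hour (60/t unless overridden)."""
        if self.review_capacity_override is not None:
            return self.review_capacity_override
        return 60.0 / self.minutes_per_review

    @property
    def capacity(self) -> float:
        return projected_capacity(self)


@dataclass(frozen=True)
class CoverageResult:
    """Demand, capacity, and coverage for one period.

    ``raw_coverage`` is 100*K/D, unbounded above (``inf`` when demand is
    zero); ``coverage`` caps it at 100; ``reported_coverage`` is the capped
    value rounded half-up to an integer percent, the figure a dashboard
    would display.
    """

    demand: float
    capacity: float
    raw_coverage: float
    coverage: float
    reported_coverage: int


@dataclass(frozen=True)
class PopulationTrajectory:
    """Per-period enrolled counts per cohort.

    ``counts`` has one row per period (index 0..horizon-1) and one column per
    cohort name, in cohort order.
    """

    counts: pd.DataFrame

    @property
    def horizon(self) -> int:
        return len(self.counts)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def projected_demand(cohorts: list[Cohort]) -> float:
    """Expected patient contacts per period: D = sum f_i * p_i * (N_i + A_i).

    Additive over cohorts and linear in each cohort's population.
    """
    return float(
        sum(
            c.review_frequency * c.contact_fraction * (c.enrolled + c.new_per_period)
            for c in cohorts
        )
    )


def projected_capacity(pool: ProviderPool) -> float:
    """Patient reviews deliverable per period: K = (60/t) * m * h."""
    return pool.reviews_per_provider_hour * pool.n_providers * pool.hours_per_period


def coverage(demand: float, capacity: float) -> CoverageResult:
    """Coverage of demand by capacity, capped at 100% for reporting.

    Zero demand is defined as fully covered (nothing to cover); the raw
    ratio is then undefined and recorded as ``inf``.
    """
    if demand < 0:
        raise InvalidParameterError("demand must be >= 0")
    if capacity < 0:
        raise InvalidParameterError("capacity must be >= 0")
    if demand == 0:
        raw = math.inf
    else:
        raw = 100.0 * capacity / demand
    capped = min(raw, 100.0)
    return CoverageResult(
        demand=demand,
        capacity=capacity,
        raw_coverage=raw,
        coverage=capped,
        reported_coverage=round_half_up(capped),
    )


def scale_coverage(
    base_coverage_pct: float, base_pool: ProviderPool, new_pool: ProviderPool
) -> float:
    """Rescale a known baseline coverage by a capacity change, capped at 100.

    Lets printed scenarios be reproduced from a reported baseline percentage
    without knowing the absolute demand: with demand fixed, coverage scales
    exactly as K_new / K_base.
    """
    if not 0.0 < base_coverage_pct <= 100.0:
        raise InvalidParameterError("base_coverage_pct must be in (0, 100]")
    ratio = projected_capacity(new_pool) / projected_capacity(base_pool)
    return min(base_coverage_pct * ratio, 100.0)


def project_population(cohorts: list[Cohort], horizon: int) -> PopulationTrajectory:
    """Project enrolled counts with N(k+1) = N(k)*(1-g) + A.

    Graduation applies before enrolment within a period.  Period 0 holds the
    initial enrolled counts; with g > 0 the count converges to A/g.
    """
    if horizon < 1:
        raise InvalidParameterError("horizon must be >= 1")
    series = {}
    for c in cohorts:
        n = float(c.enrolled)
        traj = [n]
        for _ in range(horizon - 1):
            n = n * (1.0 - c.graduation_fraction) + c.new_per_period
            traj.append(n)
        series[c.name] = traj
    return PopulationTrajectory(
        counts=pd.DataFrame(series, index=pd.RangeIndex(horizon, name="period"))
    )


@dataclass(frozen=True)
class Scenario:
    """A complete planning scenario: cohorts plus a provider pool."""

    cohorts: list[Cohort] = field(default_factory=list)
    pool: ProviderPool = None  # type: ignore[assignment]
    period_label: str = "week"

    def __post_init__(self):
        if self.pool is None:
            raise InvalidParameterError("scenario requires a provider pool")

    @property
    def demand(self) -> float:
        return projected_demand(self.cohorts)

    @property
    def capacity(self) -> float:
        return projected_capacity(self.pool)

    def coverage(self) -> CoverageResult:
        return coverage(self.demand, self.capacity)

    def with_pool(self, **changes) -> "Scenario":
        return replace(self, pool=replace(self.pool, **changes))

    @classmethod
    def from_reported_coverage(
        cls,
        pool: ProviderPool,
        reported_coverage_pct: float,
        name: str = "anchored",
        period_label: str = "week",
    ) -> "Scenario":
        """Back-solve demand from a known reported coverage percentage.

        Builds a single synthetic cohort with f = p = 1 whose population
        equals the implied demand D = 100*K / coverage, so the scenario
        reproduces the given baseline coverage exactly.
        """
        if not 0.0 < reported_coverage_pct <= 100.0:
            raise InvalidParameterError("reported coverage must be in (0, 100]")
        demand = 100.0 * projected_capacity(pool) / reported_coverage_pct
        cohort = Cohort(name=name, enrolled=demand, contact_fraction=1.0)
        return cls(cohorts=[cohort], pool=pool, period_label=period_label)
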